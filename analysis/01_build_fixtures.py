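#!/usr/bin/env python
"""Materialize the packaged study fixtures as standard files.

Writes the risk-gene screen cohort (38 exomes x 36 variants) and the
three-affected-siblings family (3 exomes x 17 variants) as VCF + PED +
annotation TSV under results/fixtures/, so every later analysis step can
also be run from files.
"""

from pathlib import Path

from aneuvar import io, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    callset, annotations = simulate.build_table2_fixture()
    (OUT / "screen_cohort.vcf").write_text(io.callset_to_vcf(callset))
    (OUT / "screen_annotations.tsv").write_text(
        io.annotations_to_tsv(annotations))
    print(f"screen cohort: {len(callset.sample_ids)} samples, "
          f"{len(callset.variants)} variants "
          f"({sum(1 for a in annotations if a.criteria_string)} published "
          "rows + decoys)")

    fam_cs, fam_ann, pedigree, controls = simulate.build_family_fixture()
    (OUT / "family.vcf").write_text(io.callset_to_vcf(fam_cs))
    (OUT / "family.ped").write_text(io.pedigree_to_ped(pedigree))
    (OUT / "family_annotations.tsv").write_text(
        io.annotations_to_tsv(fam_ann))
    n_zero = sum(1 for freqs in controls.values()
                 if all(m == 0.0 for m in freqs.values()))
    print(f"family: {len(fam_cs.sample_ids)} genotyped siblings, "
          f"{len(fam_cs.variants)} shared-candidate/decoy variants; "
          f"{n_zero} absent from all control sources")
    print(f"wrote fixtures to {OUT}")


if __name__ == "__main__":
    main()
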