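#!/usr/bin/env python
"""Screen the cohort for qualifying variants in the eight reported risk
genes (MAF <= 5% in gnomAD-all, carried by at least one patient).

Finding: 20 heterozygous missense variants in 6 of the 8 genes across 18
distinct carriers; 9 variants in PCNT alone; 4 variants recur in 2+
patients (maximum 4 carriers); 7 patients carry concomitant variants,
one of them 3.
"""

from pathlib import Path

from aneuvar import io, simulate
from aneuvar.screen import (find_concomitant, find_recurrent,
                            screen_risk_genes)

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"


def main() -> None:
    callset, annotations = simulate.build_table2_fixture()
    result = screen_risk_genes(callset, annotations,
                               list(simulate.RISK_GENE_PANEL))
    recurrent = find_recurrent(result)
    concomitant = find_concomitant(result, phase={"IA63": "trans"})

    print(f"retained {len(result.retained)} variants in "
          f"{len(result.genes_with_variants())} of {len(result.panel)} "
          f"panel genes; {len(result.distinct_carriers())} distinct carriers")
    for t in result.gene_tallies():
        print(f"  {t.gene}: {t.n_variants} variants / {t.n_carriers} patients")
    print(f"recurrent (>=2 carriers): "
          + ", ".join(f"{v.gene_symbol} {v.hgvs_c} x{n}"
                      for v, n in recurrent))
    print(f"concomitant carriers: "
          + ", ".join(f"{s} ({len(d['variants'])}, {d['phase']})"
                      for s, d in concomitant.items()))

    io.write_report({
        "screen": result.to_rows(),
        "recurrent": [{"gene": v.gene_symbol, "transcript": v.transcript_id,
                       "hgvs_c": v.hgvs_c, "carriers": n}
                      for v, n in recurrent],
        "concomitant": {s: {"n_variants": len(d["variants"]),
                            "phase": d["phase"]}
                        for s, d in concomitant.items()},
    }, OUT)
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
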