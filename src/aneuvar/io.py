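"""Readers and writers for the formats the pipeline touches.

Supported dialects
------------------
* VCF 4.2 subset: ``CHROM POS ID REF ALT QUAL FILTER INFO FORMAT samples``
  with ``FORMAT=GT`` and diploid biallelic calls.  Variant identity travels
  in INFO keys ``GENE``/``TX``/``HGVSC`` (plus optional ``HGVSP``/``RSID``)
  so that table-derived variants without genomic coordinates round-trip;
  the flag ``GENOMIC`` marks rows whose CHROM/POS/REF/ALT are real
  coordinates rather than placeholders.
* PED: whitespace-separated, >= 6 columns
  (family, individual, father, mother, sex, phenotype).
* Annotation TSV: one row per variant, header documented in
  :data:`ANNOTATION_COLUMNS`; per-source frequencies in columns
  ``<source>.maf`` / ``<source>.ac`` / ``<source>.hom`` / ``<source>.an``.

Missing values are written as ``n.a.``; ``n.a.`` and the empty string are
both accepted on read and stored as absent, never coerced to 0.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .types import (
    Affection,
    AnnotatedVariant,
    CallSet,
    Consequence,
    ConsequenceClass,
    GeneConstraint,
    GenomicPosition,
    Individual,
    Pedigree,
    PopulationFrequency,
    PredictorScores,
    SpliceEffect,
    SplicePredictor,
    VariantKey,
    Zygosity,
)

logger = logging.getLogger(__name__)

MISSING = "n.a."

REPORT_SCHEMA = "aneuvar-report/1"


class ParseError(ValueError):
    """Raised for malformed input; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


# ==========================================================================
# VCF
# ==========================================================================

_VCF_FIXED = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]


def _parse_info(info: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if info == ".":
        return out
    for item in info.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = ""
    return out


def read_callset(vcf_text: str) -> CallSet:
    """Parse a multi-sample VCF into a :class:`CallSet`.

    Zygosity derives from GT: 0/0 -> ref, 0/1 or 1/0 -> het, 1/1 -> hom.
    Missing genotypes (./.) are recorded as ref; their number is logged and
    stored on ``CallSet.missing_count``.  Multi-allelic ALT fields are
    rejected (split upstream).
    """
    samples: list[str] = []
    header_seen = False
    variants: list[VariantKey] = []
    rows: list[list[int]] = []
    missing = 0

    for lineno, raw in enumerate(vcf_text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            cols = line.split("\t")
            if cols[:8] != _VCF_FIXED:
                raise ParseError(
                    f"malformed column header: expected {_VCF_FIXED}", lineno
                )
            if len(cols) < 10 or cols[8] != "FORMAT":
                raise ParseError("FORMAT and at least one sample column "
                                 "required", lineno)
            samples = cols[9:]
            header_seen = True
            continue
        if line.startswith("#"):
            continue
        if not header_seen:
            raise ParseError("data line before #CHROM header", lineno)
        cols = line.split("\t")
        if len(cols) != 9 + len(samples):
            raise ParseError(
                f"expected {9 + len(samples)} columns, found {len(cols)}",
                lineno,
            )
        chrom, pos, vid, ref, alt, _qual, _filt, info, fmt = cols[:9]
        if "," in alt:
            raise ParseError(f"multi-allelic ALT {alt!r} not supported "
                             "(split upstream)", lineno)
        fmt_keys = fmt.split(":")
        if "GT" not in fmt_keys:
            raise ParseError("FORMAT lacks GT", lineno)
        gt_idx = fmt_keys.index("GT")

        info_map = _parse_info(info)
        genomic = None
        if "GENOMIC" in info_map:
            try:
                genomic = GenomicPosition(chrom, int(pos), ref, alt)
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
        if "GENE" in info_map:
            key = VariantKey(
                gene_symbol=info_map["GENE"],
                transcript_id=info_map.get("TX", "."),
                hgvs_c=info_map.get("HGVSC", "."),
                hgvs_p=info_map.get("HGVSP") or None,
                rsid=info_map.get("RSID") or (vid if vid != "." else None),
                genomic=genomic,
            )
        else:
            key = VariantKey(
                gene_symbol=".", transcript_id=".",
                hgvs_c=f"{chrom}:{pos}{ref}>{alt}",
                rsid=vid if vid != "." else None,
                genomic=GenomicPosition(chrom, int(pos), ref, alt),
            )

        row: list[int] = []
        for s_i, field_str in enumerate(cols[9:]):
            gt = field_str.split(":")[gt_idx]
            alleles = gt.replace("|", "/").split("/")
            if len(alleles) != 2:
                raise ParseError(
                    f"non-diploid GT {gt!r} for sample {samples[s_i]!r}",
                    lineno,
                )
            if alleles[0] == "." or alleles[1] == ".":
                missing += 1
                row.append(int(Zygosity.REF))
                continue
            try:
                a = sorted(int(x) for x in alleles)
            except ValueError as exc:
                raise ParseError(f"unparseable GT {gt!r}", lineno) from exc
            if any(x not in (0, 1) for x in a):
                raise ParseError(
                    f"allele index beyond 1 in GT {gt!r} "
                    "(multi-allelic calls must be split upstream)", lineno)
            row.append(int(Zygosity(a[0] + a[1])))
        variants.append(key)
        rows.append(row)

    if not header_seen:
        raise ParseError("no #CHROM header found")
    if missing:
        logger.warning("read_callset: %d missing genotypes recorded as "
                       "non-carrier", missing)
    matrix = (np.array(rows, dtype=np.int8).T if rows
              else np.zeros((len(samples), 0), dtype=np.int8))
    return CallSet(samples, variants, matrix, missing_count=missing)


def callset_to_vcf(callset: CallSet) -> str:
    """Serialize a CallSet to the VCF dialect :func:`read_callset` reads."""
    out = _io.StringIO()
    out.write("##fileformat=VCFv4.2\n")
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for tag, desc in (
        ("GENE", "Gene symbol"), ("TX", "RefSeq transcript"),
        ("HGVSC", "HGVS c. description"), ("HGVSP", "HGVS p. description"),
        ("RSID", "dbSNP id"),
    ):
        out.write(f'##INFO=<ID={tag},Number=1,Type=String,'
                  f'Description="{desc}">\n')
    out.write('##INFO=<ID=GENOMIC,Number=0,Type=Flag,'
              'Description="CHROM/POS/REF/ALT are real coordinates">\n')
    out.write("\t".join(_VCF_FIXED + ["FORMAT"] + list(callset.sample_ids)))
    out.write("\n")
    gt_for = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, key in enumerate(callset.variants):
        if key.genomic is not None:
            chrom, pos = key.genomic.chrom, key.genomic.pos
            ref, alt = key.genomic.ref, key.genomic.alt
            genomic_flag = ["GENOMIC"]
        else:
            chrom, pos, ref, alt = ".", j + 1, "N", "A"
            genomic_flag = []
        info_items = [f"GENE={key.gene_symbol}", f"TX={key.transcript_id}",
                      f"HGVSC={key.hgvs_c}"]
        if key.hgvs_p:
            info_items.append(f"HGVSP={key.hgvs_p}")
        if key.rsid:
            info_items.append(f"RSID={key.rsid}")
        info_items += genomic_flag
        cols = [str(chrom), str(pos), key.rsid or ".", ref, alt, ".", ".",
                ";".join(info_items), "GT"]
        cols += [gt_for[int(z)] for z in callset.zygosity[:, j]]
        out.write("\t".join(cols) + "\n")
    return out.getvalue()


# ==========================================================================
# PED
# ==========================================================================

_SEX_CODES = {"1": "male", "2": "female"}


def read_pedigree(ped_text: str, probable_affected_code: str = "3") -> Pedigree:
    """Parse PED text (>= 6 whitespace-separated columns per line).

    Phenotype codes: 2 -> affected, 1 -> unaffected, 0 or -9 -> unknown;
    ``probable_affected_code`` (default "3") -> probable_affected.
    """
    individuals: list[Individual] = []
    for lineno, raw in enumerate(ped_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise ParseError(f"expected >= 6 columns, found {len(cols)}",
                             lineno)
        fam, iid, father, mother, sex, pheno = cols[:6]
        if pheno == probable_affected_code:
            affection = Affection.PROBABLE_AFFECTED
        elif pheno == "2":
            affection = Affection.AFFECTED
        elif pheno == "1":
            affection = Affection.UNAFFECTED
        elif pheno in ("0", "-9"):
            affection = Affection.UNKNOWN
        else:
            raise ParseError(f"unknown phenotype code {pheno!r}", lineno)
        individuals.append(Individual(
            individual_id=iid,
            family_id=fam,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=_SEX_CODES.get(sex, "unknown"),
            affection=affection,
        ))
    return Pedigree(individuals)


def pedigree_to_ped(pedigree: Pedigree,
                    probable_affected_code: str = "3") -> str:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    pheno_code = {
        Affection.AFFECTED: "2",
        Affection.UNAFFECTED: "1",
        Affection.UNKNOWN: "0",
        Affection.PROBABLE_AFFECTED: probable_affected_code,
    }
    lines = []
    for ind in pedigree.individuals:
        lines.append(" ".join([
            ind.family_id, ind.individual_id,
            ind.father_id or "0", ind.mother_id or "0",
            sex_code[ind.sex], pheno_code[ind.affection],
        ]))
    return "\n".join(lines) + "\n"


# ==========================================================================
# annotation TSV
# ==========================================================================

#: fixed (non-frequency) columns of the annotation dialect
ANNOTATION_COLUMNS = [
    "gene", "transcript", "hgvs_c", "hgvs_p", "rsid",
    "consequence", "intron_offset",
    "cadd", "revel", "mcap", "clinpred", "splice",
    "mis_z", "pli", "domain_tags", "criteria",
]

_SPLICE_PRED_BY_TOKEN = {p.value: p for p in SplicePredictor}
_SPLICE_EFFECT_BY_TOKEN = {e.value: e for e in SpliceEffect}


def _is_missing(token: str) -> bool:
    return token.strip() in ("", MISSING)


def _opt_float(token: str, what: str, lineno: int) -> Optional[float]:
    if _is_missing(token):
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise ParseError(f"unparseable {what} {token!r}", lineno) from exc


def _opt_int(token: str, what: str, lineno: int) -> Optional[int]:
    if _is_missing(token):
        return None
    try:
        return int(token)
    except ValueError as exc:
        raise ParseError(f"unparseable {what} {token!r}", lineno) from exc


def _parse_splice(token: str, lineno: int) -> dict[SplicePredictor, SpliceEffect]:
    calls: dict[SplicePredictor, SpliceEffect] = {}
    if _is_missing(token):
        return calls
    for item in token.split(";"):
        item = item.strip()
        if not item:
            continue
        try:
            pred_tok, eff_tok = item.split(":")
        except ValueError as exc:
            raise ParseError(f"malformed splice call {item!r}", lineno) from exc
        pred = _SPLICE_PRED_BY_TOKEN.get(pred_tok)
        eff = _SPLICE_EFFECT_BY_TOKEN.get(eff_tok)
        if pred is None or eff is None:
            raise ParseError(f"unknown splice call {item!r}", lineno)
        if pred in calls:
            raise ParseError(f"duplicate splice predictor {pred_tok!r}", lineno)
        calls[pred] = eff
    return calls


def read_annotations(tsv_text: str) -> list[AnnotatedVariant]:
    """Parse an annotation table into :class:`AnnotatedVariant` records.

    Missing scores are stored as absent (``None``), never as 0.  Frequency
    columns are grouped by source label: ``<source>.maf`` is required for a
    source to exist on a row, counts are optional.
    """
    lines = [l for l in tsv_text.splitlines() if l.strip()]
    if not lines:
        raise ParseError("empty annotation table")
    header = lines[0].rstrip("\n").split("\t")
    col = {name: i for i, name in enumerate(header)}
    for required in ("gene", "transcript", "hgvs_c"):
        if required not in col:
            raise ParseError(f"missing identity column {required!r}", 1)
    freq_sources = sorted({
        name[: -len(".maf")] for name in header if name.endswith(".maf")
    })

    variants: list[AnnotatedVariant] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"expected {len(header)} columns, found {len(cells)}", lineno)

        def get(name: str) -> str:
            return cells[col[name]] if name in col else ""

        key = VariantKey(
            gene_symbol=get("gene"),
            transcript_id=get("transcript"),
            hgvs_c=get("hgvs_c"),
            hgvs_p=get("hgvs_p") or None if not _is_missing(get("hgvs_p")) else None,
            rsid=get("rsid") if not _is_missing(get("rsid")) else None,
        )
        cons_tok = get("consequence") or "other"
        try:
            cons_kind = Consequence(cons_tok)
        except ValueError as exc:
            raise ParseError(f"unknown consequence {cons_tok!r}", lineno) from exc
        offset = _opt_int(get("intron_offset"), "intron offset", lineno)
        try:
            consequence = ConsequenceClass(
                cons_kind,
                offset if cons_kind is Consequence.INTRONIC_BOUNDARY else None,
            )
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc

        try:
            scores = PredictorScores(
                cadd=_opt_float(get("cadd"), "CADD", lineno),
                revel=_opt_float(get("revel"), "REVEL", lineno),
                mcap=_opt_float(get("mcap"), "M-CAP", lineno),
                clinpred=_opt_float(get("clinpred"), "ClinPred", lineno),
                splice_calls=_parse_splice(get("splice"), lineno),
            )
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc

        freqs: dict[str, PopulationFrequency] = {}
        for source in freq_sources:
            maf = _opt_float(get(f"{source}.maf"), f"{source} MAF", lineno)
            if maf is None:
                continue
            try:
                freqs[source] = PopulationFrequency(
                    source=source,
                    maf=maf,
                    allele_count=_opt_int(get(f"{source}.ac"),
                                          f"{source} AC", lineno),
                    hom_count=_opt_int(get(f"{source}.hom"),
                                       f"{source} hom count", lineno),
                    total_alleles=_opt_int(get(f"{source}.an"),
                                           f"{source} AN", lineno),
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc

        mis_z = _opt_float(get("mis_z"), "misZ", lineno)
        pli = _opt_float(get("pli"), "pLI", lineno)
        constraint = (GeneConstraint(mis_z, pli)
                      if mis_z is not None and pli is not None else None)
        tags_tok = get("domain_tags")
        tags = (frozenset(t for t in tags_tok.split(";") if t)
                if not _is_missing(tags_tok) else frozenset())
        criteria = get("criteria")
        variants.append(AnnotatedVariant(
            key=key,
            consequence=consequence,
            frequencies=freqs,
            scores=scores,
            constraint=constraint,
            domain_tags=tags,
            criteria_string=None if _is_missing(criteria) else criteria,
        ))
    return variants


def annotations_to_tsv(variants: Sequence[AnnotatedVariant]) -> str:
    """Serialize annotations to the TSV dialect :func:`read_annotations`
    reads; missing values written as ``n.a.``."""
    sources = sorted({s for v in variants for s in v.frequencies})
    header = list(ANNOTATION_COLUMNS)
    for s in sources:
        header += [f"{s}.maf", f"{s}.ac", f"{s}.hom", f"{s}.an"]

    def fmt(value) -> str:
        if value is None:
            return MISSING
        if isinstance(value, float):
            return repr(value)
        return str(value)

    rows = []
    for v in variants:
        splice = ";".join(
            f"{p.value}:{e.value}"
            for p, e in sorted(v.scores.splice_calls.items(),
                               key=lambda kv: kv[0].value)
        ) or MISSING
        row = [
            v.key.gene_symbol, v.key.transcript_id, v.key.hgvs_c,
            fmt(v.key.hgvs_p), fmt(v.key.rsid),
            v.consequence.kind.value, fmt(v.consequence.intron_offset),
            fmt(v.scores.cadd), fmt(v.scores.revel), fmt(v.scores.mcap),
            fmt(v.scores.clinpred), splice,
            fmt(v.constraint.mis_z if v.constraint else None),
            fmt(v.constraint.pli if v.constraint else None),
            ";".join(sorted(v.domain_tags)) or MISSING,
            fmt(v.criteria_string),
        ]
        for s in sources:
            f = v.frequencies.get(s)
            row += [fmt(f.maf if f else None),
                    fmt(f.allele_count if f else None),
                    fmt(f.hom_count if f else None),
                    fmt(f.total_alleles if f else None)]
        rows.append(row)
    lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
    return "\n".join(lines) + "\n"


# ==========================================================================
# reports
# ==========================================================================

def _jsonify(obj):
    """Recursively coerce pipeline objects to JSON-serializable values."""
    import dataclasses
    import enum as _enum

    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj)
        if isinstance(obj, (set, frozenset)):
            items = sorted(items, key=str)
        return [_jsonify(v) for v in items]
    if isinstance(obj, _enum.Enum):
        return obj.value
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, VariantKey):
        return str(obj)
    return obj


_SORT_COLUMNS = ("gene", "transcript", "hgvs_c")


def write_report(results: Mapping[str, object], out_dir) -> list[Path]:
    """Write pipeline outputs as deterministic TSV + JSON report files.

    ``results`` maps stage names either to a list of row dicts (written as
    ``<stage>.tsv``, rows sorted by (gene, transcript, hgvs_c) when those
    columns are present) or to an arbitrary JSON-serializable summary.
    Everything is additionally collected into ``report.json`` under schema
    :data:`REPORT_SCHEMA`.  Writing the same inputs twice is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict[str, object] = {"schema": REPORT_SCHEMA, "stages": {}}

    for stage in sorted(results):
        payload = results[stage]
        if (isinstance(payload, Sequence) and not isinstance(payload, (str, bytes))
                and all(isinstance(r, Mapping) for r in payload)):
            rows = [dict(r) for r in payload]
            if rows and all(c in rows[0] for c in _SORT_COLUMNS):
                rows.sort(key=lambda r: tuple(str(r[c]) for c in _SORT_COLUMNS))
            columns: list[str] = []
            for r in rows:
                for c in r:
                    if c not in columns:
                        columns.append(c)
            lines = ["\t".join(columns)]
            for r in rows:
                lines.append("\t".join(
                    MISSING if r.get(c) is None else str(_jsonify(r.get(c)))
                    for c in columns
                ))
            path = out_dir / f"{stage}.tsv"
            path.write_text("\n".join(lines) + "\n")
            written.append(path)
            report["stages"][stage] = _jsonify(rows)  # type: ignore[index]
        else:
            report["stages"][stage] = _jsonify(payload)  # type: ignore[index]

    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    written.append(json_path)
    return written
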