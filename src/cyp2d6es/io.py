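"""Reading and writing the pipeline's tabular formats.

Genotype input is a TSV with one row per sample: ``sample_id``, one
``A/B``-style unphased call column per panel rsID (``del`` allowed for the
three deletion-allele SNPs, empty/NA for missing), ``cnv_intron6`` /
``cnv_exon9`` probe copies, and optional ``ratio_<rsID>`` variant-signal
fractions. A minimal VCF path matches biallelic records by ID and reads
unphased GT.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import pandas as pd

from .alleles import AlleleTable, _default_table
from .haplotypes import DiplotypeCall
from .types import PANEL_RSIDS, CnvCall, SnpPanelGenotype


def _parse_call(raw) -> Optional[Tuple[str, str]]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if not s or s.upper() in ("NA", "./.", "."):
        return None
    parts = s.split("/")
    if len(parts) != 2:
        raise ValueError(f"malformed call {raw!r} (expected 'A/B')")
    return (parts[0], parts[1])


def read_genotypes_tsv(
    path, table: Optional[AlleleTable] = None
) -> List[Tuple[SnpPanelGenotype, CnvCall]]:
    if table is None:
        table = _default_table()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("genotype TSV needs a sample_id column")
    out = []
    for _, row in df.iterrows():
        calls: Dict[str, Tuple[str, str]] = {}
        for r in PANEL_RSIDS:
            if r not in df.columns:
                continue
            pair = _parse_call(row[r])
            if pair is not None:
                allowed = set(table.allowed_symbols(r))
                bad = set(pair) - allowed
                if bad:
                    raise ValueError(
                        f"sample {row['sample_id']}: invalid allele {bad} "
                        f"for {r} (allowed {sorted(allowed)})"
                    )
                calls[r] = pair
        ratios = {}
        for col in df.columns:
            if col.startswith("ratio_") and not pd.isna(row[col]):
                ratios[col[len("ratio_"):]] = float(row[col])

        def probe(col):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return int(float(row[col]))

        out.append(
            (
                SnpPanelGenotype(str(row["sample_id"]), calls),
                CnvCall(probe("cnv_intron6"), probe("cnv_exon9"), ratios),
            )
        )
    return out


def read_genotypes_vcf(
    path, table: Optional[AlleleTable] = None,
    default_cnv: int = 2,
) -> List[Tuple[SnpPanelGenotype, CnvCall]]:
    """Read panel genotypes from a VCF (records matched by ID, phase ignored).

    VCF carries no CNV probe information, so every sample gets the
    ``default_cnv`` copy estimate on both probes.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    if table is None:
        table = _default_table()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: Dict[str, Dict[str, Tuple[str, str]]] = {s: {} for s in samples}
    for rec in vcf:
        rsid = rec.ID
        if rsid not in PANEL_RSIDS:
            continue
        alleles = [rec.REF] + list(rec.ALT)
        for s, gt in zip(samples, rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            ref, var = table.allowed_symbols(rsid)
            pair = tuple(
                var if alleles[i] != rec.REF else ref for i in (a, b)
            )
            calls[s][rsid] = pair  # type: ignore[assignment]
    return [
        (
            SnpPanelGenotype(s, calls[s]),
            CnvCall(default_cnv, default_cnv, {}),
        )
        for s in samples
    ]


def calls_to_frame(calls: List[Tuple[str, DiplotypeCall]]) -> pd.DataFrame:
    """Diplotype calls as the documented output table."""
    rows = []
    for sample_id, c in calls:
        d = c.diplotype
        rows.append(
            {
                "sample_id": sample_id,
                "diplotype": d.label(),
                "hap1": d.hap1.star,
                "hap2": d.hap2.star,
                "copies1": d.hap1.copies,
                "copies2": d.hap2.copies,
                "hybrid": d.hybrid_flag,
                "ambiguous": d.ambiguous or "",
                "reg_triple1": str(d.hap1.reg),
                "reg_triple2": str(d.hap2.reg),
            }
        )
    return pd.DataFrame(rows)
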