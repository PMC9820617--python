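"""MAF parsing and hotspot-status extraction for IDH1/2 and histone H3.

IDH status: a sample is *mutant* iff it carries a missense substitution at
IDH1 codon 132 or IDH2 codon 172 (the canonical glioma hotspots); any sample
present in the MAF universe without such a record is *wildtype*. A sample
absent from the MAF entirely has no genomic data and its status stays
*unknown* — that distinction is handled by :func:`fill_statuses_from_maf`.

H3 status: K27M is a Lys->Met substitution at protein position 27 or 28
(mature-protein vs initiator-Met numbering; both are accepted because MAF
annotation pipelines print K28M for what WHO nomenclature calls K27M) in
H3-3A/H3F3A, H3C2/HIST1H3B or H3C3/HIST1H3C; G34 mutation is Gly->Arg at
position 34 or 35 in H3-3A/H3F3A.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .cohort import CaseAnnotation, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "MafRecord",
    "read_maf",
    "write_maf",
    "extract_idh_status",
    "extract_h3_status",
    "mutation_status_table",
    "fill_statuses_from_maf",
]


class MafRecord(NamedTuple):
    sample_id: str
    hugo_symbol: str
    variant_classification: str
    protein_change: str


MAF_COLUMNS = {
    "Hugo_Symbol": "hugo_symbol",
    "Variant_Classification": "variant_classification",
    "HGVSp_Short": "protein_change",
    "Tumor_Sample_Barcode": "sample_id",
}

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}

_PCHANGE_RE = re.compile(r"^p\.(?:\()?([A-Za-z]{1,3}|\*)(\d+)([A-Za-z]{1,3}|\*|=)")


def _aa1(token: str) -> str | None:
    if len(token) == 1:
        return token.upper() if token != "=" else None
    return _AA3TO1.get(token.capitalize())


def parse_protein_change(pchange: str) -> tuple[str, int, str] | None:
    """Parse an HGVS short protein change into (ref, position, alt) one-letter form.

    Returns None for tokens that are not simple substitutions (frameshifts,
    splice annotations, empty strings, ...).
    """
    m = _PCHANGE_RE.match(pchange.strip())
    if m is None:
        return None
    ref, alt = _aa1(m.group(1)), _aa1(m.group(3))
    if ref is None or alt is None:
        return None
    return ref, int(m.group(2)), alt


def read_maf(path: str | Path) -> list[MafRecord]:
    """Read a MAF file (standard column names; lines starting with '#' skipped)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    for col in MAF_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"MAF is missing required column {col!r}")
    records = [
        MafRecord(
            sample_id=row.Tumor_Sample_Barcode,
            hugo_symbol=row.Hugo_Symbol,
            variant_classification=row.Variant_Classification,
            protein_change=row.HGVSp_Short,
        )
        for row in df.itertuples(index=False)
    ]
    bad = [r for r in records if not r.hugo_symbol.strip()]
    if bad:
        raise SchemaError("MAF contains rows with empty Hugo_Symbol")
    return records


def write_maf(records: Iterable[MafRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.hugo_symbol, r.variant_classification, r.protein_change, r.sample_id) for r in records],
        columns=["Hugo_Symbol", "Variant_Classification", "HGVSp_Short", "Tumor_Sample_Barcode"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _is_missense(record: MafRecord) -> bool:
    return record.variant_classification.strip().lower() == "missense_mutation"


_IDH_HOTSPOTS = {"IDH1": 132, "IDH2": 172}

_H3_K27_GENES = {"H3-3A", "H3F3A", "H3C2", "HIST1H3B", "H3C3", "HIST1H3C"}
_H3_G34_GENES = {"H3-3A", "H3F3A"}


def _sample_records(records: Sequence[MafRecord], sample_id: str) -> list[MafRecord]:
    return [r for r in records if r.sample_id == sample_id]


def extract_idh_status(records: Sequence[MafRecord], sample_id: str) -> str:
    """'mutant' iff the sample has an IDH1 R132 or IDH2 R172 missense record.

    Callers must only pass samples known to have sequencing data; absence from
    the MAF universe altogether means *unknown* and is resolved upstream.
    """
    for r in _sample_records(records, sample_id):
        gene = r.hugo_symbol.strip()
        if gene not in _IDH_HOTSPOTS or not _is_missense(r):
            continue
        parsed = parse_protein_change(r.protein_change)
        if parsed is None:
            logger.warning("unparseable protein change %r on %s row for %s; skipped",
                           r.protein_change, gene, sample_id)
            continue
        ref, pos, alt = parsed
        if pos == _IDH_HOTSPOTS[gene] and ref != alt:
            return "mutant"
    return "wildtype"


def extract_h3_status(records: Sequence[MafRecord], sample_id: str) -> str:
    """'K27M', 'G34_mut' or 'wildtype' from the sample's histone H3 records.

    K27M takes precedence over G34 if both are somehow present (logged).
    """
    k27 = g34 = False
    for r in _sample_records(records, sample_id):
        gene = r.hugo_symbol.strip()
        if gene not in _H3_K27_GENES or not _is_missense(r):
            continue
        parsed = parse_protein_change(r.protein_change)
        if parsed is None:
            logger.warning("unparseable protein change %r on %s row for %s; skipped",
                           r.protein_change, gene, sample_id)
            continue
        ref, pos, alt = parsed
        if ref == "K" and alt == "M" and pos in (27, 28):
            k27 = True
        elif gene in _H3_G34_GENES and ref == "G" and alt == "R" and pos in (34, 35):
            g34 = True
    if k27 and g34:
        logger.warning("sample %s carries both K27M and G34 H3 mutations; K27M takes precedence",
                       sample_id)
    if k27:
        return "K27M"
    if g34:
        return "G34_mut"
    return "wildtype"


def mutation_status_table(records: Sequence[MafRecord]) -> pd.DataFrame:
    """Per-sample IDH and H3 statuses for every sample present in the MAF."""
    samples = sorted({r.sample_id for r in records})
    return pd.DataFrame(
        {
            "sample_id": samples,
            "idh_status": [extract_idh_status(records, s) for s in samples],
            "h3_status": [extract_h3_status(records, s) for s in samples],
        }
    )


def fill_statuses_from_maf(
    cases: Sequence[CaseAnnotation],
    records: Sequence[MafRecord],
    sample_to_case: Mapping[str, str] | None = None,
) -> tuple[list[CaseAnnotation], dict[str, int]]:
    """Resolve unknown IDH/H3 annotation statuses from MAF records.

    For each case whose annotated status is unknown: if any MAF sample maps to
    the case, the extracted status replaces unknown; cases with no MAF sample
    at all (no genomic data) stay unknown. Returns updated copies plus counts
    of how many statuses were resolved.
    """
    sample_to_case = dict(sample_to_case or {r.sample_id: r.sample_id for r in records})
    case_samples: dict[str, list[str]] = {}
    for s in {r.sample_id for r in records}:
        case_samples.setdefault(sample_to_case.get(s, s), []).append(s)

    resolved = {"idh": 0, "h3": 0}
    updated: list[CaseAnnotation] = []
    for c in cases:
        samples = case_samples.get(c.case_id, [])
        new = CaseAnnotation(**vars(c))
        if samples:
            if c.idh_status == "unknown":
                statuses = {extract_idh_status(records, s) for s in samples}
                new.idh_status = "mutant" if "mutant" in statuses else "wildtype"
                resolved["idh"] += 1
            if c.h3_status == "unknown":
                statuses = {extract_h3_status(records, s) for s in samples}
                if "K27M" in statuses:
                    new.h3_status = "K27M"
                elif "G34_mut" in statuses:
                    new.h3_status = "G34_mut"
                else:
                    new.h3_status = "wildtype"
                resolved["h3"] += 1
        updated.append(new)
    return updated, resolved
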