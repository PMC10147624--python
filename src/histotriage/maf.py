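"""Binary gene labels from somatic-mutation (MAF) files.

A sample is labelled positive for a gene when at least one of its recorded
somatic mutations in that gene carries a VEP IMPACT of HIGH or MODERATE;
LOW/MODIFIER impacts or the absence of any record give a negative label.
The label table is complete: every (sample, gene) pair gets a 0 or 1.

Only three MAF columns are consumed (``Hugo_Symbol``,
``Tumor_Sample_Barcode``, ``IMPACT``); everything else is ignored, so any
GDC MAF version parses.  TCGA barcodes encode the tissue-source site in
their second dash-separated field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "MafRecord",
    "GeneLabelTable",
    "read_maf",
    "labels_from_maf",
    "prevalence_filter",
    "site_from_barcode",
    "patient_barcode",
]

VEP_IMPACTS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})
POSITIVE_IMPACTS = frozenset({"HIGH", "MODERATE"})
REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "IMPACT")


class MafParseError(ValueError):
    """Raised on malformed MAF content (names the offending line)."""


@dataclass(frozen=True)
class MafRecord:
    """One somatic-mutation call: gene, sample barcode, VEP impact."""

    hugo_symbol: str
    tumor_sample_barcode: str
    impact: str | None  # None for a missing IMPACT field

    def __post_init__(self) -> None:
        if self.impact is not None and self.impact not in VEP_IMPACTS:
            raise MafParseError(
                f"IMPACT {self.impact!r} outside the VEP vocabulary "
                f"{sorted(VEP_IMPACTS)}")

    @property
    def is_positive(self) -> bool:
        return self.impact in POSITIVE_IMPACTS


@dataclass
class GeneLabelTable:
    """Complete (sample, gene) -> {0,1} table as a pandas DataFrame.

    Rows are samples, columns are genes; no missing values.
    """

    table: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def genes(self) -> list[str]:
        return list(self.table.columns)

    def label(self, sample: str, gene: str) -> int:
        return int(self.table.at[sample, gene])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GeneLabelTable":
        return cls(pd.read_csv(path, index_col="sample"))


def read_maf(path: str | Path) -> list[MafRecord]:
    """Read a tab-separated MAF with a header row; ``#`` comments skipped.

    Raises :class:`MafParseError` naming the 1-based line number of any
    malformed line (wrong field count or invalid IMPACT).
    """
    path = Path(path)
    records: list[MafRecord] = []
    header: list[str] | None = None
    idx: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise MafParseError(
                        f"line {lineno}: MAF header lacks columns {missing}")
                idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
                continue
            if len(fields) != len(header):
                raise MafParseError(
                    f"line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}")
            impact = fields[idx["IMPACT"]].strip()
            try:
                records.append(MafRecord(
                    hugo_symbol=fields[idx["Hugo_Symbol"]].strip(),
                    tumor_sample_barcode=fields[idx["Tumor_Sample_Barcode"]].strip(),
                    impact=impact if impact else None,
                ))
            except MafParseError as err:
                raise MafParseError(f"line {lineno}: {err}") from None
    if header is None:
        raise MafParseError("empty MAF file (no header)")
    return records


def patient_barcode(barcode: str) -> str:
    """First three dash-separated fields (TCGA patient-level prefix)."""
    return "-".join(barcode.split("-")[:3])


def labels_from_maf(records: list[MafRecord], samples: list[str],
                    genes: list[str], *,
                    match: str = "patient") -> GeneLabelTable:
    """Build the complete binary label table from MAF records.

    A (sample, gene) pair is 1 iff at least one record for that pair has
    IMPACT HIGH or MODERATE; otherwise 0.  Record barcodes are matched to
    ``samples`` at patient level (first three barcode fields) by default,
    since mutation calls are patient-level while labels are per slide;
    ``match="exact"`` requires identical barcodes.
    """
    if not samples:
        raise ValueError("sample list must be non-empty")
    if match not in {"patient", "exact"}:
        raise ValueError(f"match must be 'patient' or 'exact', got {match!r}")

    key = patient_barcode if match == "patient" else (lambda b: b)
    sample_by_key: dict[str, list[str]] = {}
    for s in samples:
        sample_by_key.setdefault(key(s), []).append(s)

    gene_set = set(genes)
    table = pd.DataFrame(0, index=pd.Index(samples, name="sample"),
                         columns=list(genes), dtype=int)
    for rec in records:
        if not rec.is_positive or rec.hugo_symbol not in gene_set:
            continue
        for sample in sample_by_key.get(key(rec.tumor_sample_barcode), ()):
            table.at[sample, rec.hugo_symbol] = 1
    return GeneLabelTable(table)


def prevalence_filter(labels: GeneLabelTable,
                      min_prevalence: float = 0.10) -> list[str]:
    """Genes whose positive fraction strictly exceeds ``min_prevalence``.

    The denominator is the number of samples (slides) in the table; the
    inequality is strict, so a gene mutated in exactly 10% of slides is
    excluded at the default threshold.
    """
    if len(labels.table.index) == 0:
        raise ValueError("empty sample universe")
    frac = labels.table.mean(axis=0)
    return [g for g in labels.genes if frac[g] > min_prevalence]


def site_from_barcode(barcode: str) -> str:
    """Tissue-source-site code: field 2 of a TCGA barcode.

    ``TCGA-A7-A0CE-01Z-00-DX1`` -> ``A7``.  Non-TCGA or malformed barcodes
    raise :class:`MafParseError`.
    """
    fields = barcode.split("-")
    if len(fields) < 2 or fields[0] != "TCGA" or not fields[1]:
        raise MafParseError(f"not a TCGA barcode: {barcode!r}")
    return fields[1]
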