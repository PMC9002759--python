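"""Packaged inventory of sunflower AW-box motifs with EMSA binding labels.

The shipped TSV transcribes the published motif tables for genes of the
plastidial fatty-acid synthesis pathway: each row is one motif instance with
its sequence, strand, TIS-relative span, 5'-UTR flag, whether it was tested
by electrophoretic mobility shift assay (EMSA) and with what outcome
(bound / unbound / smear / untested).  Rows whose table-printed span is
internally inconsistent with the motif length carry a note in the source
column; the identity of one member of the bound training set is provisional
(the definitive roster exists only as figure colouring) and is flagged as
such in its source field.

Labels: "bound" = clear band shift; "unbound" = clear negative; "smear" =
ambiguous lane suggesting weak binding, held out of both classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .coords import span_length
from .pattern import insertion_offsets, matches_canonical

__all__ = ["AWBoxRecord", "load_fixtures", "select", "genes_with_k_bound_boxes",
           "EMSA_LABELS"]

EMSA_LABELS = ("bound", "unbound", "smear", "untested")
_VARIANTS = ("canonical", "insertion", "mutant")


@dataclass(frozen=True)
class AWBoxRecord:
    """One motif instance from the packaged inventory."""

    gene_name: str
    seq: str
    strand: str
    tis_start: int | None
    tis_end: int | None
    in_utr5: bool
    tested_in_emsa: bool
    emsa_label: str
    variant: str
    insertion_offset: int | None
    source: str

    def __post_init__(self) -> None:
        if self.emsa_label not in EMSA_LABELS:
            raise ValueError(f"{self.gene_name}: unknown emsa_label {self.emsa_label!r}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"{self.gene_name}: unknown variant {self.variant!r}")
        if self.variant == "canonical" and not matches_canonical(self.seq):
            raise ValueError(f"{self.gene_name}: {self.seq} violates the canonical pattern")
        if self.variant == "insertion" and not insertion_offsets(self.seq):
            raise ValueError(f"{self.gene_name}: {self.seq} is not a one-insertion variant")
        if self.variant != "mutant" and self.tis_start is not None:
            if span_length(self.tis_start, self.tis_end) != len(self.seq):
                raise ValueError(f"{self.gene_name}: span {self.tis_start}/{self.tis_end}"
                                 f" inconsistent with {len(self.seq)}-mer")

    @property
    def position_label(self) -> str:
        if self.tis_start is None:
            return self.gene_name
        return f"{self.gene_name} {self.tis_start}"


def _parse_row(row: dict, lineno: int) -> AWBoxRecord:
    try:
        return AWBoxRecord(
            gene_name=row["gene_name"],
            seq=row["seq"].upper(),
            strand=row["strand"],
            tis_start=int(row["tis_start"]) if row["tis_start"] else None,
            tis_end=int(row["tis_end"]) if row["tis_end"] else None,
            in_utr5=row["in_utr5"] == "Y",
            tested_in_emsa=row["tested_in_emsa"] == "Y",
            emsa_label=row["emsa_label"],
            variant=row["variant"],
            insertion_offset=int(row["insertion_offset"]) if row["insertion_offset"] else None,
            source=row["source"],
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed fixture row {lineno}: {exc}") from exc


def load_fixtures() -> list[AWBoxRecord]:
    """Load and validate every record of the packaged motif inventory."""
    import csv

    text = resources.files("awbox").joinpath("data/awbox_motifs.tsv").read_text()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    return [_parse_row(row, i) for i, row in enumerate(reader, start=2)]


def select(records: list[AWBoxRecord],
           tested_only: bool = False,
           label_filter: str | None = None,
           canonical_only: bool = False) -> list[AWBoxRecord]:
    """Filtered subset of records, input order preserved."""
    if label_filter is not None and label_filter not in EMSA_LABELS:
        raise ValueError(f"unknown emsa_label {label_filter!r}; "
                         f"expected one of {EMSA_LABELS}")
    out = []
    for r in records:
        if tested_only and not r.tested_in_emsa:
            continue
        if canonical_only and r.variant != "canonical":
            continue
        if label_filter is not None and r.emsa_label != label_filter:
            continue
        out.append(r)
    return out


def genes_with_k_bound_boxes(records: list[AWBoxRecord], k: int) -> list[str]:
    """Gene names with at least ``k`` motifs labelled bound."""
    counts: dict[str, int] = {}
    for r in records:
        if r.emsa_label == "bound" and r.variant != "mutant":
            counts[r.gene_name] = counts.get(r.gene_name, 0) + 1
    return sorted(g for g, n in counts.items() if n >= k)
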