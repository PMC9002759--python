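"""FASTA and sidecar-TSV input/output for promoter sets.

Promoter sequences travel as plain FASTA (written and parsed with Biopython);
their TIS annotation travels in a tab-separated sidecar with columns
``gene_id``, ``tis_index`` (promoter-local, 0-based index of the A of the
ATG) and optional ``utr5_start`` (TIS-relative, negative).
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scan import PromoterSequence

__all__ = ["read_promoters", "write_promoters", "write_fixture_fasta",
           "write_hits_tsv", "write_hits_bed", "write_truth_tsv"]

SIDECAR_COLUMNS = ("gene_id", "tis_index", "utr5_start")


def write_promoters(promoters, fasta_path, sidecar_path) -> None:
    records = [SeqRecord(Seq(p.seq), id=p.gene_id, description="") for p in promoters]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(sidecar_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(SIDECAR_COLUMNS)
        for p in promoters:
            w.writerow([p.gene_id, p.tis_index,
                        "" if p.utr5_start is None else p.utr5_start])


def read_promoters(fasta_path, sidecar_path) -> list[PromoterSequence]:
    meta: dict[str, dict] = {}
    with open(sidecar_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["gene_id"]] = row
    promoters = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta:
            raise ValueError(f"no TIS sidecar entry for sequence {rec.id!r}")
        row = meta[rec.id]
        utr5 = row.get("utr5_start") or ""
        promoters.append(PromoterSequence(
            gene_id=rec.id,
            seq=str(rec.seq),
            tis_index=int(row["tis_index"]),
            utr5_start=int(utr5) if utr5 else None,
        ))
    return promoters


def write_fixture_fasta(records, path) -> None:
    """Export fixture motif sequences as FASTA (one entry per record)."""
    out = []
    for r in records:
        pos = "" if r.tis_start is None else f"_{r.tis_start}"
        name = f"{r.gene_name}{pos}".replace(" ", "_")
        out.append(SeqRecord(Seq(r.seq), id=name,
                             description=f"{r.emsa_label} {r.variant}"))
    SeqIO.write(out, str(path), "fasta")


def write_hits_tsv(hits, path) -> None:
    from .scan import hits_to_records
    rows = hits_to_records(hits)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, delimiter="\t", fieldnames=list(rows[0].keys()) if rows else
                           ["gene_id", "tis_start", "tis_end", "strand", "variant",
                            "matched_seq", "local_start", "local_end", "insertion_offset"])
        w.writeheader()
        w.writerows(rows)


def write_hits_bed(hits, path) -> None:
    """BED6 in promoter-local 0-based half-open coordinates."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.local_start}\t{h.local_end}\t"
                     f"{h.gene_id}:{h.tis_start}\t0\t{h.strand}\n")


def write_truth_tsv(records, path) -> None:
    cols = ["gene_name", "seq", "strand", "tis_start", "tis_end", "in_utr5",
            "tested_in_emsa", "emsa_label", "variant", "insertion_offset", "source"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(cols)
        for r in records:
            w.writerow([r.gene_name, r.seq, r.strand,
                        "" if r.tis_start is None else r.tis_start,
                        "" if r.tis_end is None else r.tis_end,
                        "Y" if r.in_utr5 else "N",
                        "Y" if r.tested_in_emsa else "N",
                        r.emsa_label, r.variant,
                        "" if r.insertion_offset is None else r.insertion_offset,
                        r.source])
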