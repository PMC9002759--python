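"""Seeded generator of promoter sequences with planted AW boxes and decoys.

Backgrounds are drawn i.i.d. from a configurable base composition; boxes from
the packaged bound/unbound pools, explicit sequences, forbidden-base decoys
or extra-base insertion variants are planted at controlled TIS distances and
strands, overwriting the background without shifting coordinates.  The same
seed and configuration always produce byte-identical sequences and truth
records, so every pipeline stage can be tested end to end without external
data.

By default the sequenced region extends 51 bp past the ATG (the TIS sits 51
bases before the 3' end), so TIS-crossing coordinate arithmetic is exercised
by ordinary use.

A canonical AW box fixes 5 of 14 positions, so under a uniform composition a
background window matches by chance about once per 4^5 = 1024 bp per strand;
evaluations therefore compare scanner output against the truth records
rather than asserting that no incidental hits exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coords import span_end, tis_to_index
from .fixtures import AWBoxRecord, load_fixtures, select
from .pattern import N_SLOTS, matches_canonical, reverse_complement

__all__ = ["PlantSpec", "SimConfig", "simulate", "make_decoy"]

_SOURCES = ("bound-pool", "unbound-pool", "explicit", "forbidden-decoy",
            "insertion-variant")


@dataclass(frozen=True)
class PlantSpec:
    """One box to plant in every simulated promoter.

    ``tis_distance`` is either a single TIS-relative start coordinate or an
    inclusive (low, high) range to sample from; coordinates follow the
    no-zero convention.
    """

    source: str = "bound-pool"
    seq: str | None = None                  # for source == "explicit"
    tis_distance: int | tuple[int, int] = (-200, -80)
    strand: str = "+"
    decoy_n_index: int | None = None        # for source == "forbidden-decoy"
    decoy_base: str | None = None

    def __post_init__(self) -> None:
        if self.source not in _SOURCES:
            raise ValueError(f"unknown plant source {self.source!r}")
        if self.source == "explicit" and not self.seq:
            raise ValueError("explicit plants need a seq")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class SimConfig:
    n_promoters: int = 10
    promoter_length: int = 1000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted: tuple[PlantSpec, ...] = ()
    seed: int = 0
    tis_offset_from_end: int = 51  # TIS sits this many bases before the 3' end

    def __post_init__(self) -> None:
        comp = tuple(float(x) for x in self.base_composition)
        object.__setattr__(self, "base_composition", comp)
        object.__setattr__(self, "planted", tuple(self.planted))
        if len(comp) != 4 or not np.isclose(sum(comp), 1.0):
            raise ValueError("base_composition must be 4 frequencies summing to 1")
        if not 0 <= self.tis_offset_from_end <= self.promoter_length:
            raise ValueError("TIS offset outside the promoter")

    @property
    def tis_index(self) -> int:
        return self.promoter_length - self.tis_offset_from_end


def make_decoy(base_box: str, forbidden_position: int, base: str) -> str:
    """Single substitution at an N slot producing a known-violation negative."""
    base = base.upper()
    if forbidden_position not in range(1, 10):
        raise ValueError(f"N index must be 1..9, got {forbidden_position}")
    if base not in "ACGT":
        raise ValueError(f"invalid base {base!r}")
    if len(base_box) != 14 or not matches_canonical(base_box):
        raise ValueError(f"{base_box!r} is not a canonical AW box")
    slot = N_SLOTS[forbidden_position - 1]
    if base_box[slot] == base:
        raise ValueError(f"substitution at N{forbidden_position} equals the "
                         f"original base {base!r}: not a decoy")
    out = base_box[:slot] + base + base_box[slot + 1:]
    assert matches_canonical(out)
    return out


def _pool(label: str) -> list[str]:
    records = load_fixtures()
    return [r.seq for r in select(records, tested_only=True,
                                  label_filter=label, canonical_only=True)]


def _insertion_pool() -> list[str]:
    return [r.seq for r in load_fixtures()
            if r.variant == "insertion" and r.tis_start is not None]


def _plant_seq(spec: PlantSpec, rng: np.random.Generator,
               pools: dict[str, list[str]]) -> str:
    if spec.source == "explicit":
        return spec.seq.upper()
    if spec.source == "forbidden-decoy":
        base_box = spec.seq.upper() if spec.seq else \
            pools["bound"][int(rng.integers(len(pools["bound"])))]
        if spec.decoy_n_index is None or spec.decoy_base is None:
            raise ValueError("forbidden-decoy plants need decoy_n_index and decoy_base")
        return make_decoy(base_box, spec.decoy_n_index, spec.decoy_base)
    if spec.source == "insertion-variant":
        return pools["insertion"][int(rng.integers(len(pools["insertion"])))]
    pool = pools["bound" if spec.source == "bound-pool" else "unbound"]
    return pool[int(rng.integers(len(pool)))]


def _sample_start(spec: PlantSpec, seq_len: int, cfg: SimConfig,
                  rng: np.random.Generator) -> int:
    if isinstance(spec.tis_distance, (tuple, list)):
        lo, hi = spec.tis_distance
        for _ in range(200):
            start = int(rng.integers(lo, hi + 1))
            if start != 0:
                local = tis_to_index(start, cfg.tis_index)
                if 0 <= local and local + seq_len <= cfg.promoter_length:
                    return start
        raise ValueError(f"infeasible placement for planted item {spec}")
    start = int(spec.tis_distance)
    local = tis_to_index(start, cfg.tis_index)
    if local < 0 or local + seq_len > cfg.promoter_length:
        raise ValueError(f"infeasible placement for planted item {spec}")
    return start


_LABEL_FOR_SOURCE = {
    "bound-pool": "bound",
    "unbound-pool": "unbound",
    "forbidden-decoy": "unbound",
    "insertion-variant": "bound",
    "explicit": "untested",
}


def simulate(config: SimConfig):
    """Generate promoters plus ground-truth records for every planted box.

    Returns ``(promoters, truth)`` where promoters are
    :class:`~awbox.scan.PromoterSequence` and truth records are
    :class:`~awbox.fixtures.AWBoxRecord` with exact spans and strands.
    Placement that cannot satisfy the fit/non-overlap constraints raises an
    error naming the planted item.
    """
    from .scan import PromoterSequence  # local import to avoid cycle

    rng = np.random.default_rng(config.seed)
    pools = {}
    if any(s.source in ("bound-pool", "forbidden-decoy") for s in config.planted):
        pools["bound"] = _pool("bound")
    if any(s.source == "unbound-pool" for s in config.planted):
        pools["unbound"] = _pool("unbound")
    if any(s.source == "insertion-variant" for s in config.planted):
        pools["insertion"] = _insertion_pool()

    bases = np.array(list("ACGT"))
    promoters, truth = [], []
    for p in range(config.n_promoters):
        gene_id = f"sim_{p:03d}"
        arr = rng.choice(bases, size=config.promoter_length,
                         p=config.base_composition)
        occupied: list[tuple[int, int]] = []
        for spec in config.planted:
            seq = _plant_seq(spec, rng, pools)
            for attempt in range(200):
                tis_start = _sample_start(spec, len(seq), config, rng)
                local = tis_to_index(tis_start, config.tis_index)
                span = (local, local + len(seq))
                if all(span[1] <= a or span[0] >= b for a, b in occupied):
                    break
                if not isinstance(spec.tis_distance, (tuple, list)):
                    raise ValueError(f"planted item overlaps another: {spec}")
            else:
                raise ValueError(f"no non-overlapping placement found for {spec}")
            occupied.append(span)
            planted = seq if spec.strand == "+" else reverse_complement(seq)
            arr[span[0]: span[1]] = list(planted)
            truth.append(AWBoxRecord(
                gene_name=gene_id, seq=seq, strand=spec.strand,
                tis_start=tis_start, tis_end=span_end(tis_start, len(seq)),
                in_utr5=False, tested_in_emsa=False,
                emsa_label=_LABEL_FOR_SOURCE[spec.source],
                variant="insertion" if len(seq) == 15 else "canonical",
                insertion_offset=None,
                source=f"simulated:{spec.source}",
            ))
        promoters.append(PromoterSequence(gene_id, "".join(arr),
                                          tis_index=config.tis_index))
    return promoters, truth
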