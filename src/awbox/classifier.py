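"""Rule-based prediction of WRI1 binding for candidate AW boxes.

The mechanism is the forbidden-base rule: a candidate is predicted
non-bindable when it carries, at any variable slot, a base never observed in
the bound training set.  Three modes are offered:

* ``strict-forbidden`` — reject iff a forbidden base is present (the
  mechanism the binding data directly support);
* ``allowed-profile`` — reject iff any N base falls outside the set observed
  in training (identical to strict-forbidden by construction, kept as a
  separate named mode because the two diverge if the allowed sets are edited
  by hand);
* ``pwm-threshold`` — rank candidates by log-odds score against a bit
  threshold (no experimentally anchored default).

Insertion variants (15-mers with one extra internal base) are not forced
through the canonical rule: binding of such a box was demonstrated
experimentally but the matrices are trained on canonical 14-mers only, so
they are flagged "non-canonical, bindable-precedent" unless canonical_only
handling is requested.

Probe construction and the point-mutagenesis operations used to build EMSA
probes are also provided here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures import AWBoxRecord
from .matrices import (
    DEFAULT_PSEUDOCOUNT,
    ForbiddenReport,
    build_pfm,
    build_ppm,
    build_pwm,
    forbidden_and_bias,
    score_sequence,
)
from .pattern import (
    MOTIF_LENGTH,
    N_SLOTS,
    insertion_offsets,
    matches_canonical,
    n_bases,
    reverse_complement,
)

__all__ = ["ClassifierProfile", "Prediction", "fit_profile", "predict",
           "mutate_n_position", "substitute_inserted_base", "build_probe",
           "Probe", "evaluate", "MODES"]

MODES = ("strict-forbidden", "allowed-profile", "pwm-threshold")

# N index (1..9) -> 0-based motif slot; the mapping every operation shares.
N_TO_SLOT = {k: slot for k, slot in enumerate(N_SLOTS, start=1)}


@dataclass(frozen=True)
class ClassifierProfile:
    """Allowed/bias base sets learned from the bound training set."""

    allowed: dict[int, frozenset[str]]          # N index -> observed bases
    bias: dict[int, frozenset[str]]             # N index -> modal base(s)
    max_distance: int = 500
    require_utr5: bool = False
    mode: str = "strict-forbidden"
    pwm_threshold: float | None = None
    pwm_weights: tuple | None = None            # serialisable PWM cells
    background: tuple = (0.25, 0.25, 0.25, 0.25)

    def forbidden(self, n_index: int) -> frozenset[str]:
        return frozenset("ACGT") - self.allowed[n_index]

    def to_dict(self) -> dict:
        return {
            "allowed": {k: sorted(v) for k, v in self.allowed.items()},
            "bias": {k: sorted(v) for k, v in self.bias.items()},
            "max_distance": self.max_distance,
            "require_utr5": self.require_utr5,
            "mode": self.mode,
            "pwm_threshold": self.pwm_threshold,
            "pwm_weights": self.pwm_weights,
            "background": list(self.background),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierProfile":
        return cls(
            allowed={int(k): frozenset(v) for k, v in d["allowed"].items()},
            bias={int(k): frozenset(v) for k, v in d["bias"].items()},
            max_distance=d.get("max_distance", 500),
            require_utr5=d.get("require_utr5", False),
            mode=d.get("mode", "strict-forbidden"),
            pwm_threshold=d.get("pwm_threshold"),
            pwm_weights=tuple(map(tuple, d["pwm_weights"])) if d.get("pwm_weights") else None,
            background=tuple(d.get("background", (0.25,) * 4)),
        )


@dataclass(frozen=True)
class Prediction:
    label: str                       # "bindable" | "not-bindable"
    reasons: tuple[str, ...] = ()
    score: float | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ("bindable", "not-bindable"):
            raise ValueError(f"invalid label {self.label!r}")


def fit_profile(bound_seqs,
                max_distance: int = 500,
                require_utr5: bool = False,
                mode: str = "strict-forbidden",
                pseudocount: float = DEFAULT_PSEUDOCOUNT,
                background=(0.25, 0.25, 0.25, 0.25),
                pwm_threshold: float | None = None) -> ClassifierProfile:
    """Learn allowed/bias sets from canonical bound 14-mers."""
    seqs = [r.seq if isinstance(r, AWBoxRecord) else r for r in bound_seqs]
    if not seqs:
        raise ValueError("cannot fit a profile on an empty training set")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    pfm = build_pfm(seqs)
    report: ForbiddenReport = forbidden_and_bias(pfm)
    pwm = build_pwm(build_ppm(pfm, pseudocount), background)
    return ClassifierProfile(
        allowed={k: report.allowed(k) for k in report.forbidden},
        bias=dict(report.bias),
        max_distance=max_distance,
        require_utr5=require_utr5,
        mode=mode,
        pwm_threshold=pwm_threshold,
        pwm_weights=tuple(map(tuple, pwm.weights.tolist())),
        background=tuple(pwm.background.tolist()),
    )


def _rule_reasons(profile: ClassifierProfile, seq: str, strict: bool) -> list[str]:
    reasons = []
    for k, base in n_bases(seq).items():
        if strict:
            bad = base in profile.forbidden(k)
        else:
            bad = base not in profile.allowed[k]
        if bad:
            reasons.append(f"{base} at N{k} is forbidden "
                           f"(allowed: {''.join(sorted(profile.allowed[k]))})")
    return reasons


def predict(profile: ClassifierProfile, record, mode: str | None = None) -> Prediction:
    """Classify one candidate box (an AWBoxRecord, a MotifHit, or a 14/15-mer).

    Coordinates, when present on the record, are additionally gated on
    distance to the TIS; every violated rule contributes one reason string.
    """
    mode = mode or profile.mode
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    seq = record if isinstance(record, str) else record.seq if hasattr(record, "seq") \
        else record.matched_seq
    tis_start = getattr(record, "tis_start", None)

    if len(seq) == MOTIF_LENGTH + 1:
        if not insertion_offsets(seq):
            raise ValueError(f"{seq!r} is neither canonical nor a one-insertion variant")
        return Prediction("bindable", (),
                          note="non-canonical, bindable-precedent: one-extra-base "
                               "variant, outside the canonical rule's domain")
    if not matches_canonical(seq):
        raise ValueError(f"{seq!r} does not match the canonical AW-box pattern")

    reasons: list[str] = []
    score = None
    if mode == "pwm-threshold":
        if profile.pwm_weights is None:
            raise ValueError("profile carries no PWM weights")
        weights = np.asarray(profile.pwm_weights, dtype=float)
        from .matrices import PositionWeightMatrix
        score = score_sequence(
            PositionWeightMatrix(weights, np.asarray(profile.background)), seq)
        threshold = profile.pwm_threshold
        if threshold is None:
            raise ValueError("pwm-threshold mode needs a threshold in bits")
        if score < threshold:
            reasons.append(f"log-odds score {score:.2f} bits below threshold {threshold:.2f}")
    else:
        reasons = _rule_reasons(profile, seq, strict=(mode == "strict-forbidden"))

    if tis_start is not None and abs(tis_start) > profile.max_distance:
        reasons.append(f"distance {abs(tis_start)} bp from TIS exceeds "
                       f"max_distance {profile.max_distance}")
    label = "not-bindable" if reasons else "bindable"
    return Prediction(label, tuple(reasons), score)


def mutate_n_position(seq: str, n_index: int, base: str,
                      insertion_offset: int | None = None) -> str:
    """Substitute the base at variable slot N1..N9 of a 14- or 15-mer.

    For 15-mer insertion variants the slot is located in the underlying
    canonical frame, skipping the extra base at ``insertion_offset``.
    """
    base = base.upper()
    if base not in "ACGT":
        raise ValueError(f"invalid base {base!r}")
    if n_index not in N_TO_SLOT:
        raise ValueError(f"N index must be 1..9, got {n_index}")
    slot = N_TO_SLOT[n_index]
    if len(seq) == MOTIF_LENGTH:
        pass
    elif len(seq) == MOTIF_LENGTH + 1:
        if insertion_offset is None:
            offs = insertion_offsets(seq)
            if not offs:
                raise ValueError(f"{seq!r} is not a one-insertion variant")
            insertion_offset = offs[0]
        if slot >= insertion_offset - 1:
            slot += 1
    else:
        raise ValueError("sequence must be a 14-mer or a 15-mer insertion variant")
    return seq[:slot] + base + seq[slot + 1:]


def substitute_inserted_base(seq: str, base: str, insertion_offset: int | None = None) -> str:
    """Replace the extra base of a 15-mer insertion variant."""
    base = base.upper()
    if base not in "ACGT":
        raise ValueError(f"invalid base {base!r}")
    if len(seq) != MOTIF_LENGTH + 1:
        raise ValueError("substitute_inserted_base needs a 15-mer insertion variant")
    if insertion_offset is None:
        offs = insertion_offsets(seq)
        if not offs:
            raise ValueError(f"{seq!r} is not a one-insertion variant")
        insertion_offset = offs[0]
    i = insertion_offset - 1
    return seq[:i] + base + seq[i + 1:]


@dataclass(frozen=True)
class Probe:
    """Double-stranded EMSA probe: motif plus flanking context."""

    top: str
    bottom: str
    box_start: int  # 0-based offset of the box within the top strand

    def __post_init__(self) -> None:
        if reverse_complement(self.top) != self.bottom:
            raise ValueError("probe strands are not exact reverse complements")

    def __len__(self) -> int:
        return len(self.top)


def build_probe(box_seq: str, flank_length: int = 5,
                flanks: tuple[str, str] | None = None,
                seed: int | None = None) -> Probe:
    """Assemble a probe of length len(box) + 2*flank_length.

    Flanks are either given explicitly or drawn uniformly at random from a
    seeded generator (reproducible across runs).
    """
    if flank_length < 0:
        raise ValueError("flank_length must be >= 0")
    if flanks is not None:
        left, right = flanks
        if len(left) != flank_length or len(right) != flank_length:
            raise ValueError("given flanks must have length flank_length")
    elif flank_length == 0:
        left = right = ""
    else:
        rng = np.random.default_rng(seed)
        draw = rng.choice(list("ACGT"), size=2 * flank_length)
        left = "".join(draw[:flank_length])
        right = "".join(draw[flank_length:])
    top = (left + box_seq + right).upper()
    return Probe(top, reverse_complement(top), flank_length)


def evaluate(profile: ClassifierProfile, records,
             mode: str | None = None) -> dict:
    """Score labelled records and tabulate the confusion plus explanations.

    Records labelled "smear" are reported separately and never scored;
    insertion variants are routed to the bindable-precedent path and listed
    in the explanation table with their note.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot evaluate an empty record list")
    mode = mode or profile.mode
    rows, smears = [], []
    confusion = {"bound": {"bindable": 0, "not-bindable": 0},
                 "unbound": {"bindable": 0, "not-bindable": 0}}
    for r in records:
        if r.emsa_label == "smear":
            smears.append(r)
            continue
        if r.emsa_label not in ("bound", "unbound"):
            raise ValueError(f"{r.gene_name}: unlabeled record in scoring set "
                             f"(emsa_label={r.emsa_label!r})")
        pred = predict(profile, r.seq, mode=mode)
        confusion[r.emsa_label][pred.label] += 1
        rows.append({
            "gene": r.gene_name,
            "position": "" if r.tis_start is None else r.tis_start,
            "seq": r.seq,
            "emsa_label": r.emsa_label,
            "prediction": pred.label,
            "agrees": (r.emsa_label == "bound") == (pred.label == "bindable"),
            "reasons": "; ".join(pred.reasons),
            "note": pred.note or "",
        })
    table = pd.DataFrame(rows)
    smear_table = pd.DataFrame(
        [{"gene": r.gene_name,
          "position": "" if r.tis_start is None else r.tis_start,
          "seq": r.seq} for r in smears])
    n_bound = sum(confusion["bound"].values())
    n_unbound = sum(confusion["unbound"].values())
    return {
        "mode": mode,
        "confusion": confusion,
        "sensitivity": confusion["bound"]["bindable"] / n_bound if n_bound else float("nan"),
        "specificity": confusion["unbound"]["not-bindable"] / n_unbound if n_unbound else float("nan"),
        "explanations": table,
        "smears_held_out": smear_table,
    }
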