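"""Model/Results interface for the AW-box binding-site analysis.

``BindingSiteModel`` is built from the motifs that bound the transcription
factor in the shift assays; ``fit()`` derives the position matrices, the
forbidden-base and bias report, the IUPAC consensus and a classifier
profile, and returns a ``BindingSiteResults`` carrying them together with
``predict``, ``evaluate`` and a ``summary()`` table.

    >>> from awbox import fixtures, model
    >>> records = fixtures.load_fixtures()
    >>> res = model.BindingSiteModel.from_records(records).fit()
    >>> res.consensus
    'CHTCGWKWAYWYCG'
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import classifier as _clf
from . import matrices as _mat
from .fixtures import AWBoxRecord, select

__all__ = ["BindingSiteModel", "BindingSiteResults"]


class BindingSiteModel:
    """Position-matrix model of transcription-factor binding to the AW box.

    Parameters
    ----------
    bound_seqs
        Canonical 14-mers that clearly bound the factor (the training set).
    background
        Genomic background base frequencies (ACGT) used for the log-odds
        matrix; uniform by default because the sunflower genomic frequencies
        are not part of the shipped data.
    """

    def __init__(self, bound_seqs, background=(0.25, 0.25, 0.25, 0.25)):
        self.bound_seqs = [s.seq if isinstance(s, AWBoxRecord) else str(s).upper()
                           for s in bound_seqs]
        if not self.bound_seqs:
            raise ValueError("the training set is empty")
        self.background = tuple(float(b) for b in background)

    @classmethod
    def from_records(cls, records, background=(0.25, 0.25, 0.25, 0.25)):
        """Build the model from labelled records, keeping clear canonical positives."""
        bound = select(records, tested_only=True, label_filter="bound",
                       canonical_only=True)
        return cls(bound, background=background)

    def fit(self,
            pseudocount: float = _mat.DEFAULT_PSEUDOCOUNT,
            include_threshold: float = _mat.DEFAULT_INCLUDE_THRESHOLD,
            collapse_threshold: float = _mat.DEFAULT_COLLAPSE_THRESHOLD,
            max_distance: int = 500,
            mode: str = "strict-forbidden") -> "BindingSiteResults":
        """Derive matrices, forbidden/bias report, consensus and profile."""
        pfm = _mat.build_pfm(self.bound_seqs)
        ppm = _mat.build_ppm(pfm, pseudocount=0.0)          # raw: zeros are signal
        ppm_pwm = _mat.build_ppm(pfm, pseudocount=pseudocount)
        pwm = _mat.build_pwm(ppm_pwm, self.background)
        report = _mat.forbidden_and_bias(pfm)
        consensus = _mat.iupac_consensus(ppm, "bias-collapse",
                                         include_threshold, collapse_threshold)
        profile = _clf.fit_profile(self.bound_seqs, max_distance=max_distance,
                                   mode=mode, pseudocount=pseudocount,
                                   background=self.background)
        return BindingSiteResults(self, pfm, ppm, ppm_pwm, pwm, report,
                                  consensus, profile,
                                  include_threshold, collapse_threshold)


@dataclass
class BindingSiteResults:
    """Fitted matrices, derived consensus and classifier for the AW box."""

    model: BindingSiteModel
    pfm: _mat.PositionFrequencyMatrix
    ppm: _mat.PositionProbabilityMatrix          # pseudocount 0
    ppm_smoothed: _mat.PositionProbabilityMatrix  # pseudocounted, feeds the PWM
    pwm: _mat.PositionWeightMatrix
    forbidden_report: _mat.ForbiddenReport
    consensus: str
    profile: _clf.ClassifierProfile
    include_threshold: float
    collapse_threshold: float

    @property
    def n_sequences(self) -> int:
        return self.pfm.n_sequences

    def predict(self, record, mode: str | None = None) -> _clf.Prediction:
        return _clf.predict(self.profile, record, mode=mode)

    def score(self, seq: str) -> float:
        return _mat.score_sequence(self.pwm, seq)

    def evaluate(self, records, mode: str | None = None) -> dict:
        return _clf.evaluate(self.profile, records, mode=mode)

    def matrices_frame(self) -> pd.DataFrame:
        """PFM counts, PPM probabilities and PWM weights in one tidy table."""
        rows = []
        for slot in range(14):
            for j, base in enumerate(_mat.BASES):
                rows.append({
                    "position": slot + 1,
                    "base": base,
                    "count": int(self.pfm.counts[slot, j]),
                    "probability": float(self.ppm.probs[slot, j]),
                    "weight_bits": float(self.pwm.weights[slot, j]),
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of the fitted motif model."""
        rep = self.forbidden_report
        lines = [
            "AW-box binding-site model",
            "=" * 54,
            f"training sequences (clear EMSA positives): {self.n_sequences}",
            f"background (ACGT): {tuple(round(b, 4) for b in self.model.background)}",
            f"PWM pseudocount: {self.ppm_smoothed.pseudocount}",
            f"consensus (include>={self.include_threshold}, "
            f"collapse>={self.collapse_threshold}): {self.consensus}",
            "",
            "pos  forbidden  bias (prob)",
        ]
        for k in sorted(rep.forbidden):
            forb = "".join(sorted(rep.forbidden[k])) or "-"
            bias = "".join(sorted(rep.bias[k]))
            lines.append(f" N{k}  {forb:<9}  {bias} ({rep.bias_probability[k]:.2f})")
        lines.append("")
        lines.append(_mat.text_logo(self.ppm))
        return "\n".join(lines)

    def to_meme(self, name: str = "AW-box") -> str:
        return _mat.to_meme_minimal(self.ppm_smoothed, name=name,
                                    background=self.model.background,
                                    n_sequences=self.n_sequences)
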