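"""ROC calibration of k-mer similarity scores against alignment identity.

Query-subject pairs are labeled true when their alignment identity
(pairwise identities divided by the shorter length) reaches a threshold,
conventionally 0.97 — the usual OTU boundary.  Sweeping the similarity
cutoff over the observed scores yields a TPR/FPR curve per k-mer size;
the calibrated cutoff is the highest one achieving a target TPR.

Pairs in the truth table that the search did not return enter with score
0, so missed positives count against the TPR rather than inflating it.
Counting is per-pair.  Producing the identity labels themselves (an
aligner's job) is out of scope: this module consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, TextIO, Union

import numpy as np

DEFAULT_IDENTITY_THRESHOLD = 0.97


class DegenerateLabelsError(ValueError):
    """All-true or all-false labels: one of TPR/FPR is undefined."""


class CutoffUnreachableError(ValueError):
    """No cutoff achieves the requested TPR."""


def alignment_identity(i: int, lq: int, ls: int) -> float:
    """Identity fraction: pairwise identities over the shorter length."""
    if lq < 1 or ls < 1:
        raise ValueError(f"lengths must be >= 1, got ({lq}, {ls})")
    shorter = min(lq, ls)
    if not 0 <= i <= shorter:
        raise ValueError(f"identity count {i} outside [0, {shorter}]")
    return i / shorter


@dataclass(frozen=True)
class LabeledPair:
    query_id: str
    subject_id: str
    score_percent: float
    identity_fraction: float
    is_true: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError(f"identity fraction {self.identity_fraction} outside [0, 1]")


@dataclass(frozen=True)
class RocCurve:
    """TPR/FPR per similarity cutoff, cutoffs strictly descending."""

    k: int
    points: Tuple[Tuple[float, float, float], ...]  # (cutoff, TPR, FPR)

    def auc(self) -> float:
        """Trapezoidal area under the curve, anchored at (0,0) and (1,1)."""
        fpr = [0.0] + [p[2] for p in self.points] + [1.0]
        tpr = [0.0] + [p[1] for p in self.points] + [1.0]
        return float(np.trapezoid(tpr, fpr))


def label_pairs(identities: Mapping[Tuple[str, str], float],
                scores: Mapping[Tuple[str, str], float],
                identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> List[LabeledPair]:
    """Join the identity truth table with search scores.

    Every pair in ``identities`` is a candidate; a pair absent from
    ``scores`` gets score 0.  Scored pairs absent from the truth table
    are ignored (no label exists for them).
    """
    pairs = []
    for key, identity in identities.items():
        query_id, subject_id = key
        pairs.append(
            LabeledPair(
                query_id=query_id,
                subject_id=subject_id,
                score_percent=float(scores.get(key, 0.0)),
                identity_fraction=float(identity),
                is_true=identity >= identity_threshold,
            )
        )
    return pairs


def roc_curve(pairs: Iterable[LabeledPair], k: int) -> RocCurve:
    """One (cutoff, TPR, FPR) point per distinct observed score, plus the
    0-cutoff extreme where everything is called positive.

    TPR at a cutoff is the fraction of true pairs with score >= cutoff;
    FPR likewise over false pairs.
    """
    pair_list = list(pairs)
    scores = np.array([p.score_percent for p in pair_list], dtype=np.float64)
    truth = np.array([p.is_true for p in pair_list], dtype=bool)
    n_true = int(truth.sum())
    n_false = len(pair_list) - n_true
    if n_true == 0 or n_false == 0:
        raise DegenerateLabelsError(
            f"need both labels, got {n_true} true and {n_false} false pairs"
        )
    cutoffs = sorted(set(scores.tolist()), reverse=True)
    if not cutoffs or cutoffs[-1] > 0.0:
        cutoffs.append(0.0)
    points = []
    for cutoff in cutoffs:
        called = scores >= cutoff
        tpr = float((called & truth).sum()) / n_true
        fpr = float((called & ~truth).sum()) / n_false
        points.append((float(cutoff), tpr, fpr))
    return RocCurve(k=k, points=tuple(points))


def cutoff_for_tpr(curve: RocCurve, target_tpr: float) -> Tuple[float, float, float]:
    """Highest cutoff whose TPR >= ``target_tpr``; returns (cutoff,
    achieved TPR, FPR).  Raises :class:`CutoffUnreachableError` if even
    cutoff 0 falls short."""
    if not 0.0 < target_tpr <= 1.0:
        raise ValueError(f"target TPR must be in (0, 1], got {target_tpr}")
    for cutoff, tpr, fpr in curve.points:  # cutoffs descend, TPR ascends
        if tpr >= target_tpr:
            return cutoff, tpr, fpr
    raise CutoffUnreachableError(
        f"maximum TPR {curve.points[-1][1]:.4f} below target {target_tpr}"
    )


# ---------------------------------------------------------------------------
# TSV plumbing

def read_identity_tsv(source: Union[str, TextIO]) -> Dict[Tuple[str, str], float]:
    """Read a labeled-pair table: query_id <tab> subject_id <tab>
    identity_fraction, "#" lines ignored."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_identity_tsv(fh)
    identities: Dict[Tuple[str, str], float] = {}
    for line in source:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed identity row: {line!r}")
        identities[(parts[0], parts[1])] = float(parts[2])
    return identities


def write_roc_tsv(curve: RocCurve, dest: Union[str, TextIO],
                  provenance: Optional[Mapping[str, object]] = None) -> None:
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            write_roc_tsv(curve, fh, provenance=provenance)
            return
    if provenance:
        for key, value in provenance.items():
            dest.write(f"# {key}={value}\n")
    dest.write("#cutoff\ttpr\tfpr\n")
    for cutoff, tpr, fpr in curve.points:
        dest.write(f"{cutoff:.2f}\t{tpr:.6f}\t{fpr:.6f}\n")


def format_cutoff_report(k: int, cutoff: float, tpr: float, fpr: float) -> str:
    return f"k={k}\tcutoff={cutoff:.2f}\ttpr={tpr:.4f}\tfpr={fpr:.4f}"
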