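"""Ranked-screen validation metrics: EF at fixed fractions, ROC-AUC, RIE, BEDROC.

The evaluation follows the standard early-recognition literature: the merged
active/decoy library is sorted by descending fit value; enrichment factors
EF_f = (a_f/n_f)/(A/N) are reported at fractions f (default 1%, 5%, 10%)
with the cutoff n_f = round-half-up(f*N); ROC-AUC comes from the rank-sum
(Mann-Whitney) identity with mid-rank tie handling; RIE and BEDROC use the
Truchon-Bayly exponential weighting with early-recognition parameter alpha
(default 20).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

LABEL_ACTIVE = "active"
LABEL_DECOY = "decoy"
# the serialization convention of the validation protocol: 2 = active, 1 = decoy
_NUMERIC_LABELS = {"1": LABEL_DECOY, "2": LABEL_ACTIVE, LABEL_ACTIVE: LABEL_ACTIVE, LABEL_DECOY: LABEL_DECOY}


@dataclass(frozen=True)
class RankedEntry:
    """One scored library member; higher score = better pharmacophore fit."""

    id: str
    score: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in (LABEL_ACTIVE, LABEL_DECOY):
            raise ValueError(f"label must be 'active' or 'decoy', got {self.label!r}")
        if math.isnan(self.score):
            raise ValueError("score must not be NaN")


@dataclass
class RankedScreen:
    """Entries sorted by descending score, with tie bookkeeping.

    ``tie_groups`` lists (start, end) half-open index ranges of runs of
    equal scores with length > 1. ``degenerate`` is True when the screen is
    empty or contains only one label; metric operations refuse such screens.
    """

    entries: list[RankedEntry]
    tie_groups: list[tuple[int, int]] = field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.entries)

    @property
    def A(self) -> int:
        return sum(1 for e in self.entries if e.label == LABEL_ACTIVE)

    @property
    def degenerate(self) -> bool:
        return self.N == 0 or self.A == 0 or self.A == self.N

    def scores(self) -> np.ndarray:
        return np.asarray([e.score for e in self.entries], dtype=float)

    def is_active(self) -> np.ndarray:
        return np.asarray([e.label == LABEL_ACTIVE for e in self.entries], dtype=bool)


@dataclass
class EnrichmentReport:
    """All validation metrics for one screen."""

    N: int
    A: int
    fractions: list[float]
    n_f: dict[float, int]
    a_f: dict[float, int]
    ef: dict[float, float]
    auc: float
    rie_alpha: float
    bedroc_alpha: float
    alpha: float

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "A": self.A,
            "fractions": self.fractions,
            "cutoff_counts": {str(f): self.n_f[f] for f in self.fractions},
            "active_counts": {str(f): self.a_f[f] for f in self.fractions},
            "enrichment_factors": {str(f): round(self.ef[f], 2) for f in self.fractions},
            "enrichment_factors_full": {str(f): self.ef[f] for f in self.fractions},
            "roc_auc": self.auc,
            "rie": self.rie_alpha,
            "bedroc": self.bedroc_alpha,
            "alpha": self.alpha,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def format_text(self) -> str:
        """Human-readable validation summary."""
        lines = [
            f"Screen of {self.N} molecules ({self.A} actives, {self.N - self.A} decoys).",
        ]
        for f in self.fractions:
            lines.append(
                f"  top {f:.0%}: {self.a_f[f]} active molecules among the top "
                f"{self.n_f[f]} ranked molecules -> EF {self.ef[f]:.2f}"
            )
        lines.append(f"  ROC-AUC {self.auc:.3f}; RIE {self.rie_alpha:.3f} and "
                     f"BEDROC {self.bedroc_alpha:.3f} at alpha={self.alpha:g}")
        return "\n".join(lines)


def rank_screen(entries: Iterable[RankedEntry]) -> RankedScreen:
    """Stable descending sort with tie-group bookkeeping."""
    ordered = sorted(entries, key=lambda e: -e.score)
    tie_groups: list[tuple[int, int]] = []
    i = 0
    while i < len(ordered):
        j = i + 1
        while j < len(ordered) and ordered[j].score == ordered[i].score:
            j += 1
        if j - i > 1:
            tie_groups.append((i, j))
        i = j
    return RankedScreen(entries=ordered, tie_groups=tie_groups)


def topk_count(N: int, f: float) -> int:
    """Cutoff count for fraction f: nearest integer to f*N, halves up,
    clamped to [1, N]."""
    if not 0 < f < 1:
        raise ValueError(f"fraction must lie in (0,1), got {f}")
    if N < 1:
        raise ValueError("N must be >= 1")
    n = math.floor(f * N + 0.5)
    return min(max(n, 1), N)


def enrichment_factor(a_f: int, n_f: int, A: int, N: int) -> float:
    """EF = (a_f/n_f)/(A/N), full precision (round for reporting only)."""
    if n_f <= 0 or A <= 0:
        raise ValueError("n_f and A must be positive")
    if not (0 <= a_f <= n_f <= N):
        raise ValueError("require 0 <= a_f <= n_f <= N")
    return (a_f / n_f) / (A / N)


def _check_labels(rs: RankedScreen) -> None:
    if rs.degenerate:
        raise ValueError("degenerate_labels")


def _ascending_midranks(rs: RankedScreen) -> np.ndarray:
    """Mid-ranks of the scores in ascending-score convention (worst = 1)."""
    return rankdata(rs.scores(), method="average")


def roc_auc(rs: RankedScreen) -> float:
    """ROC-AUC via the rank-sum identity with mid-ranks for ties.

    AUC = (R_active - A(A+1)/2) / (A*(N-A)) where R_active is the sum of
    the actives' ascending-score mid-ranks; identical to trapezoidal ROC
    integration and to the normalized Mann-Whitney U statistic.
    """
    _check_labels(rs)
    ranks = _ascending_midranks(rs)
    A, N = rs.A, rs.N
    r_active = float(ranks[rs.is_active()].sum())
    return (r_active - A * (A + 1) / 2) / (A * (N - A))


def rie(rs: RankedScreen, alpha: float = 20.0) -> float:
    """Robust initial enhancement at early-recognition parameter alpha.

    RIE = (1/A) * sum_i exp(-alpha*r_i/N) / [(1/N)*(1-e^-alpha)/(e^(alpha/N)-1)]
    over the actives' descending ranks r_i (best = 1); ties take the
    group's average rank. RIE = 1 in expectation for a random ranking.
    """
    _check_labels(rs)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    N, A = rs.N, rs.A
    desc_ranks = N + 1 - _ascending_midranks(rs)  # mid-ranks, best = 1
    s = float(np.exp(-alpha * desc_ranks[rs.is_active()] / N).sum())
    random_mean = (1 / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)
    return (s / A) / random_mean


def bedroc(rs: RankedScreen, alpha: float = 20.0) -> float:
    """BEDROC: RIE rescaled to [0, 1].

    BEDROC = RIE * Ra*sinh(alpha/2) / [cosh(alpha/2) - cosh(alpha/2 - alpha*Ra)]
             + 1 / (1 - e^(alpha*(1-Ra)))     with Ra = A/N.
    Converges to ROC-AUC as alpha -> 0+.
    """
    _check_labels(rs)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    ra = rs.A / rs.N
    factor = ra * math.sinh(alpha / 2) / (math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
    value = rie(rs, alpha) * factor + 1 / (1 - math.exp(alpha * (1 - ra)))
    # guard against 1e-15-scale overshoot at the perfect-screen boundary
    return min(max(value, 0.0), 1.0)


def actives_in_top(rs: RankedScreen, n: int) -> int:
    """Actives among the top n of the stable descending order.

    A tie group straddling the cutoff is resolved by the stable sort order;
    the ambiguity is reported via boundary_tie_warning().
    """
    return int(rs.is_active()[:n].sum())


def boundary_tie_warning(rs: RankedScreen, n: int) -> str | None:
    for start, end in rs.tie_groups:
        if start < n < end:
            return (
                f"tie group spanning ranks {start + 1}..{end} crosses the top-{n} "
                "boundary; counts follow stable input order"
            )
    return None


def evaluate_screen(
    rs: RankedScreen,
    fractions: Sequence[float] = (0.01, 0.05, 0.10),
    alpha: float = 20.0,
) -> EnrichmentReport:
    """Assemble the full validation report for a ranked screen."""
    _check_labels(rs)
    fractions = sorted(fractions)
    n_f: dict[float, int] = {}
    a_f: dict[float, int] = {}
    ef: dict[float, float] = {}
    for f in fractions:
        n = topk_count(rs.N, f)
        a = actives_in_top(rs, n)
        n_f[f], a_f[f] = n, a
        ef[f] = enrichment_factor(a, n, rs.A, rs.N)
    return EnrichmentReport(
        N=rs.N,
        A=rs.A,
        fractions=list(fractions),
        n_f=n_f,
        a_f=a_f,
        ef=ef,
        auc=roc_auc(rs),
        rie_alpha=rie(rs, alpha),
        bedroc_alpha=bedroc(rs, alpha),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_scores_csv(path: str | Path) -> list[RankedEntry]:
    """Score table ``id,score,label`` with label in {1,2} (1 = decoy,
    2 = active) or {decoy,active}."""
    entries: list[RankedEntry] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = row["label"].strip().lower()
            if raw not in _NUMERIC_LABELS:
                raise ValueError(f"unknown label {row['label']!r} for id {row['id']!r}")
            entries.append(RankedEntry(id=row["id"], score=float(row["score"]), label=_NUMERIC_LABELS[raw]))
    return entries


def write_scores_csv(entries: Iterable[RankedEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "score", "label"])
        for e in entries:
            writer.writerow([e.id, repr(e.score), "2" if e.label == LABEL_ACTIVE else "1"])
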