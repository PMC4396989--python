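"""Effect-size metrics and the four-class switching-pattern classifier.

Usage ratios, not raw counts, carry the switching signal: site *j*'s usage
ratio in a sample is its read count divided by the sample's total for the
gene, and the per-site ratio change is

    delta_j = ratio_sample2_j - ratio_sample1_j

(positive = the site gained usage, "up"; negative = "down"). From these the
module derives:

* **DiffInRatio** — the sum of squared per-site ratio changes, a
  nonnegative, sample-symmetric measure of how much the whole usage
  profile moved (0 for identical profiles, at most 2 for disjoint ones);
* the **normalized average 3'-UTR length** per sample — the count-weighted
  mean 3'-UTR length divided by the most distal site's length, and its
  between-sample change (signed, sample2 - sample1);
* the **switching-pattern label**: near-zero deltas are absorbed into
  their stronger neighbor, consecutive same-sign deltas are summed into
  runs, and the resulting alternating sign sequence names the pattern —
  "+-" is up-down (/\\, 3'-UTR shortening), "-+" is down-up (\\/,
  lengthening), "+-+" (/\\/) and "-+-" (\\/\\) are the complex patterns in
  which the middle sites move against both flanks. One change point means
  simple regulation, two means complex regulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .io import TandemGene

logger = logging.getLogger("apaswitch")

# pattern labels
SHORTENING = "/\\"
LENGTHENING = "\\/"
UP_DOWN_UP = "/\\/"
DOWN_UP_DOWN = "\\/\\"
OTHER = "other"
NONE = "none"

PATTERN_LABELS = (SHORTENING, LENGTHENING, UP_DOWN_UP, DOWN_UP_DOWN, OTHER, NONE)

_SIGN_TO_LABEL = {
    "+-": SHORTENING,
    "-+": LENGTHENING,
    "+-+": UP_DOWN_UP,
    "-+-": DOWN_UP_DOWN,
}


class ZeroTotalError(ValueError):
    """A sample has no reads for the gene; usage ratios are undefined."""


@dataclass(frozen=True)
class UsageProfile:
    """Per-site usage ratios for both samples and their difference."""

    ratios_sample1: tuple[float, ...]
    ratios_sample2: tuple[float, ...]

    @property
    def delta(self) -> tuple[float, ...]:
        return tuple(b - a for a, b in zip(self.ratios_sample1, self.ratios_sample2))

    @classmethod
    def from_gene(cls, gene: TandemGene) -> "UsageProfile":
        t1, t2 = gene.total_sample1, gene.total_sample2
        if t1 == 0 or t2 == 0:
            raise ZeroTotalError(
                f"{gene.gene_id}: usage ratios undefined (sample totals {t1}, {t2})"
            )
        return cls(
            tuple(c / t1 for c in gene.counts_sample1),
            tuple(c / t2 for c in gene.counts_sample2),
        )

    @classmethod
    def from_deltas(cls, deltas: Sequence[float]) -> "UsageProfile":
        """Build a profile from ratio changes alone (for classification).

        Sample 1 is taken as uniform usage; deltas must sum to ~0 and keep
        every implied ratio within [0, 1].
        """
        k = len(deltas)
        if k < 2:
            raise ValueError("need at least two sites")
        if abs(sum(deltas)) > 1e-9:
            raise ValueError("ratio changes must sum to zero")
        base = [1.0 / k] * k
        r2 = [b + d for b, d in zip(base, deltas)]
        if any(x < -1e-12 or x > 1 + 1e-12 for x in r2):
            raise ValueError("deltas imply usage ratios outside [0, 1]")
        return cls(tuple(base), tuple(min(1.0, max(0.0, x)) for x in r2))


def diff_in_ratio(gene: TandemGene, sqrt: bool = False) -> float:
    """Differential APA site usage: sum over sites of the squared usage-ratio
    difference between the two samples.

    Zero iff the usage profiles coincide; bounded by 2 (disjoint profiles).
    With ``sqrt=True`` the Euclidean (root-sum-square) variant is returned;
    the two orderings of genes are identical, only the scale differs.
    """
    prof = UsageProfile.from_gene(gene)
    val = sum((a - b) ** 2 for a, b in zip(prof.ratios_sample1, prof.ratios_sample2))
    return math.sqrt(val) if sqrt else val


@dataclass(frozen=True)
class LengthChange:
    norm_len_sample1: float
    norm_len_sample2: float
    change: float


def normalized_length_change(gene: TandemGene) -> LengthChange:
    """Normalized average 3'-UTR length per sample and its change.

    The average is the count-weighted mean of the site 3'-UTR lengths,
    normalized by the most distal length, hence in (0, 1]; the change is
    sample2 - sample1 (negative = shortening). Group comparisons typically
    use the absolute value.
    """
    t1, t2 = gene.total_sample1, gene.total_sample2
    if t1 == 0 or t2 == 0:
        raise ZeroTotalError(
            f"{gene.gene_id}: average length undefined (sample totals {t1}, {t2})"
        )
    lmax = gene.utr_lengths[-1]
    n1 = sum(c * l for c, l in zip(gene.counts_sample1, gene.utr_lengths)) / t1 / lmax
    n2 = sum(c * l for c, l in zip(gene.counts_sample2, gene.utr_lengths)) / t2 / lmax
    return LengthChange(n1, n2, n2 - n1)


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternCall:
    """Classifier output: the merged alternating-sign delta runs, their sign
    string, and the pattern label."""

    merged_deltas: tuple[float, ...]
    sign_string: str
    label: str


def _is_near_zero(d: float, epsilon: float) -> bool:
    return abs(d) < epsilon or d == 0.0


def classify_pattern(
    profile: UsageProfile,
    epsilon: float = 0.05,
    collapse: bool = False,
) -> PatternCall:
    """Classify a gene's switching pattern from its usage-ratio changes.

    Procedure:

    1. deltas with absolute value below ``epsilon`` are dealt with first:
       leading and trailing near-zeros are dropped, interior ones are
       absorbed (summed) into the neighbor with the larger absolute change,
       smallest first;
    2. consecutive same-sign deltas are summed into single runs;
    3. the alternating sign sequence is mapped to a label: "+-" -> /\\
       (shortening), "-+" -> \\/ (lengthening), "+-+" -> /\\/,
       "-+-" -> \\/\\. Longer alternations are reported as "other" unless
       ``collapse`` is set, in which case the weakest run is repeatedly
       folded into its stronger neighbor until one of the four classes (or
       a single run) remains. If every delta is near zero the label is
       "none".
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    deltas = list(profile.delta)
    if len(deltas) < 2:
        raise ValueError("pattern classification needs at least two sites")

    deltas = _absorb_near_zeros(deltas, epsilon)
    if not deltas:
        return PatternCall((), "", NONE)
    runs = _merge_sign_runs(deltas)
    # absorption can re-create sub-epsilon runs at the edges; treat an
    # all-weak outcome as no pattern rather than forcing a label
    if all(_is_near_zero(r, epsilon) for r in runs):
        return PatternCall(tuple(runs), _signs(runs), NONE)
    if collapse:
        while len(runs) > 3:
            runs = _fold_weakest_run(runs)
    sign_string = _signs(runs)
    if len(runs) == 1:
        label = NONE  # no change point: residual one-sided drift only
    else:
        label = _SIGN_TO_LABEL.get(sign_string, OTHER)
    return PatternCall(tuple(runs), sign_string, label)


def classify_gene(gene: TandemGene, epsilon: float = 0.05, collapse: bool = False) -> PatternCall:
    """Convenience wrapper: classify a gene's pattern from its counts."""
    return classify_pattern(UsageProfile.from_gene(gene), epsilon=epsilon, collapse=collapse)


def _signs(values: Sequence[float]) -> str:
    return "".join("+" if v > 0 else "-" for v in values)


def _absorb_near_zeros(deltas: list[float], epsilon: float) -> list[float]:
    deltas = list(deltas)
    while True:
        while deltas and _is_near_zero(deltas[0], epsilon):
            deltas.pop(0)
        while deltas and _is_near_zero(deltas[-1], epsilon):
            deltas.pop()
        interior = [i for i in range(1, len(deltas) - 1) if _is_near_zero(deltas[i], epsilon)]
        if not interior:
            return deltas
        i = min(interior, key=lambda j: abs(deltas[j]))
        j = i - 1 if abs(deltas[i - 1]) >= abs(deltas[i + 1]) else i + 1
        deltas[j] += deltas[i]
        del deltas[i]


def _merge_sign_runs(deltas: Sequence[float]) -> list[float]:
    runs: list[float] = [deltas[0]]
    for d in deltas[1:]:
        if (d > 0) == (runs[-1] > 0):
            runs[-1] += d
        else:
            runs.append(d)
    return runs


def _fold_weakest_run(runs: list[float]) -> list[float]:
    i = min(range(len(runs)), key=lambda j: abs(runs[j]))
    if i == 0:
        j = 1
    elif i == len(runs) - 1:
        j = i - 1
    else:
        j = i - 1 if abs(runs[i - 1]) >= abs(runs[i + 1]) else i + 1
    out = list(runs)
    out[j] += out[i]
    del out[i]
    return _merge_sign_runs(out)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    exact_max_n: int = 20,
) -> dict[tuple[str, str], float]:
    """Pairwise two-sided Wilcoxon rank-sum tests between groups.

    For every pair of groups (in mapping order) the two-sided
    Mann-Whitney/Wilcoxon rank-sum p-value is computed: exact when both
    groups are smaller than ``exact_max_n`` and tie-free, otherwise the
    tie-corrected normal approximation. Empty groups are skipped with a
    warning.
    """
    out: dict[tuple[str, str], float] = {}
    names = [g for g in values_by_group if len(values_by_group[g]) > 0]
    for g in values_by_group:
        if len(values_by_group[g]) == 0:
            logger.warning("group %s is empty; skipping its comparisons", g)
    for a, b in combinations(names, 2):
        x = np.asarray(values_by_group[a], dtype=float)
        y = np.asarray(values_by_group[b], dtype=float)
        pooled = np.concatenate([x, y])
        tie_free = np.unique(pooled).size == pooled.size
        if len(x) < exact_max_n and len(y) < exact_max_n and tie_free:
            method = "exact"
        else:
            method = "asymptotic"
        p = mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        out[(a, b)] = float(min(1.0, p))
    return out
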