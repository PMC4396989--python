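"""Simulated tandem-APA genes: worked examples and randomized cohorts.

Two kinds of synthetic data are provided.

**Worked examples** (:func:`example_gene`): fifteen deterministic
three-site genes, arranged in three scenarios, that demonstrate when the
linear trend test is blind to switching that the independence test sees:

* ``T1`` — the middle site sits exactly at the mean 3'-UTR length of the
  flanks (1000/2500/4000 nt) and only the middle site's expression
  changes, so the average 3'-UTR length is unchanged and the trend p is 1
  no matter how extreme the switch;
* ``T2`` — the same counts (100,100,100 vs 100,500,100) while the middle
  site's distance sweeps from 2000 to 3000 nt, showing the trend p rise to
  1 as the middle approaches the flank mean and fall symmetrically beyond;
* ``T3`` — middle-vs-flank switches tuned so the count-weighted average
  3'-UTR length (lengths 1000/2000/4000 nt) is preserved despite gross
  profile changes, again leaving the trend test powerless.

**Random cohorts** (:func:`simulate_cohort`): reproducible multinomial
read counts at fixed per-sample depth, with sample 2's site probabilities
perturbed according to a planted pattern (or not, for null/type-I
calibration). Defaults mirror the worked examples' geometry: uniform
baseline usage and evenly spaced 3'-UTR lengths from 1000 to 4000 nt, so
that for three sites the middle site lies at the flank mean and the
complex patterns preserve the expected average 3'-UTR length.
"""

from __future__ import annotations

import numpy as np

from .io import TandemGene

# --- worked-example scenarios ---------------------------------------------

_T1_LENGTHS = (1000, 2500, 4000)
_T1_ROWS: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...] = (
    ((100, 100, 100), (100, 100, 100)),
    ((100, 100, 100), (100, 500, 100)),
    ((100, 100, 100), (100, 1000, 100)),
    ((100, 100, 100), (10, 100, 10)),
    ((100, 100, 100), (1000, 100, 1000)),
)

_T2_COUNTS = ((100, 100, 100), (100, 500, 100))
_T2_LENGTH_ROWS: tuple[tuple[int, int, int], ...] = (
    (1000, 2000, 4000),
    (1000, 2300, 4000),
    (1000, 2500, 4000),
    (1000, 2700, 4000),
    (1000, 3000, 4000),
)

_T3_LENGTHS = (1000, 2000, 4000)
_T3_ROWS: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...] = (
    ((100, 100, 100), (10, 960, 200)),
    ((100, 100, 100), (100, 600, 200)),
    ((100, 100, 100), (100, 1100, 300)),
    ((100, 100, 100), (100, 4600, 1000)),
    ((100, 100, 100), (50, 300, 100)),
)

SCENARIOS = ("T1", "T2", "T3")


def example_gene(scenario: str, row: int) -> TandemGene:
    """Return one deterministic worked-example gene.

    ``scenario`` is "T1", "T2" or "T3" (see module docstring); ``row`` is
    the 1-based row index within the scenario (1..5).
    """
    scenario = scenario.upper()
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if not 1 <= row <= 5:
        raise ValueError(f"{scenario} has rows 1..5, got {row}")
    if scenario == "T1":
        lengths, (c1, c2) = _T1_LENGTHS, _T1_ROWS[row - 1]
    elif scenario == "T2":
        lengths, (c1, c2) = _T2_LENGTH_ROWS[row - 1], _T2_COUNTS
    else:
        lengths, (c1, c2) = _T3_LENGTHS, _T3_ROWS[row - 1]
    return TandemGene(f"{scenario}_row{row}", lengths, c1, c2)


def all_example_genes() -> list[TandemGene]:
    """All fifteen worked-example genes, in scenario/row order."""
    return [example_gene(s, r) for s in SCENARIOS for r in range(1, 6)]


# --- randomized cohorts ----------------------------------------------------

EFFECTS = ("null", "shortening", "lengthening", "up_down_up", "down_up_down")

#: expected pattern label produced by each planted effect
EFFECT_LABELS = {
    "shortening": "/\\",
    "lengthening": "\\/",
    "up_down_up": "/\\/",
    "down_up_down": "\\/\\",
}


def _site_lengths(k: int) -> tuple[int, ...]:
    # evenly spaced 1000..4000 nt; for k=3 this is the equal-flank geometry
    return tuple(int(round(x)) for x in np.linspace(1000, 4000, k))


def effect_probabilities(k: int, effect: str, effect_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Baseline and perturbed per-site usage probabilities for a planted
    effect on ``k`` sites.

    Baseline is uniform. ``effect_size`` is the total probability mass
    moved: shortening moves it onto the proximal site (taken equally from
    all others), lengthening onto the distal site; up_down_up moves it off
    the interior site(s) onto the two flanks equally, down_up_down the
    reverse. The complex effects preserve the expected average 3'-UTR
    length under the evenly spaced site geometry.
    """
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}; expected one of {EFFECTS}")
    if not 0 <= effect_size < 1:
        raise ValueError("effect_size must lie in [0, 1)")
    if k < 2:
        raise ValueError("need at least two sites")
    if effect in ("up_down_up", "down_up_down") and k < 3:
        raise ValueError(f"effect {effect!r} needs at least three sites")
    base = np.full(k, 1.0 / k)
    p2 = base.copy()
    e = effect_size
    if effect == "shortening":
        p2[0] += e
        p2[1:] -= e / (k - 1)
    elif effect == "lengthening":
        p2[-1] += e
        p2[:-1] -= e / (k - 1)
    elif effect == "up_down_up":
        p2[0] += e / 2
        p2[-1] += e / 2
        p2[1:-1] -= e / (k - 2)
    elif effect == "down_up_down":
        p2[0] -= e / 2
        p2[-1] -= e / 2
        p2[1:-1] += e / (k - 2)
    if (p2 < 0).any():
        raise ValueError(
            f"effect_size {effect_size} too large for {k} sites ({effect}): "
            "a site probability would go negative"
        )
    return base, p2


def simulate_cohort(
    n_genes: int,
    effect: str = "null",
    effect_size: float = 0.0,
    depth: int = 300,
    site_count_range: tuple[int, int] = (3, 3),
    seed: int | None = None,
    gene_prefix: str | None = None,
) -> list[TandemGene]:
    """Generate a reproducible cohort of simulated tandem-APA genes.

    Per gene, the site count is drawn uniformly from
    ``site_count_range`` (inclusive), sample 1's counts are multinomial
    over the uniform baseline probabilities and sample 2's over the
    effect-perturbed probabilities, each at ``depth`` reads per sample.
    A null effect uses identical probabilities for both samples. The same
    seed yields an identical cohort.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if depth <= 0:
        raise ValueError("depth must be positive")
    lo, hi = site_count_range
    if not 2 <= lo <= hi:
        raise ValueError("site_count_range must satisfy 2 <= lo <= hi")
    rng = np.random.default_rng(seed)
    prefix = gene_prefix if gene_prefix is not None else f"sim_{effect}"
    # validate the effect once per possible site count
    probs = {k: effect_probabilities(k, effect, effect_size) for k in range(lo, hi + 1)}
    genes: list[TandemGene] = []
    width = max(4, len(str(n_genes)))
    for i in range(n_genes):
        k = int(rng.integers(lo, hi + 1))
        p1, p2 = probs[k]
        c1 = rng.multinomial(depth, p1)
        c2 = rng.multinomial(depth, p2)
        genes.append(TandemGene(
            f"{prefix}_{i:0{width}d}",
            _site_lengths(k),
            tuple(int(x) for x in c1),
            tuple(int(x) for x in c2),
        ))
    return genes
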