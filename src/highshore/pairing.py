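"""Random-pairing null model for sexed two-animal associations.

High-shore littorinid snails form two-animal associations whose sex
composition carries behavioral information: trail-following pairs (a
*tracker* snail following the mucus trail of a *marker*) and two-snail
*towers* (one snail resting on top of another).  To ask whether a
particular sex combination dominates — e.g. males following females on a
rising tide, consistent with mate searching — the observed counts of the
four ordered combinations are compared with the counts expected if pairs
formed at random from the sampled pool of individuals.

With ``m`` males and ``n`` females in the pool, each individual equally
likely to take either role, the expected numbers of the four ordered
combinations (key ``XY`` = role-1 sex ``X``, role-2 sex ``Y``; role 1 is
the marker or the bottom animal, role 2 the tracker or the top animal) are

    E[FM] = n * 0.5 * m / (m + n - 1)
    E[MM] = m * 0.5 * (m - 1) / (m + n - 1)
    E[MF] = m * 0.5 * n / (m + n - 1)
    E[FF] = n * 0.5 * (n - 1) / (m + n - 1)

These are the pair-level expectations of drawing two individuals without
replacement from the pool and assigning roles by a fair coin.  The four
values sum to ``N = (m + n) / 2`` pairs identically, and the two mixed
combinations always have equal expectation.

The sampling model behind the null is fixed throughout this module as a
*uniform perfect matching* of all ``m + n`` individuals into ``N`` pairs
followed by an independent fair orientation of each pair.  Both oracles
(:func:`exact_enumeration`, :func:`monte_carlo_null`) implement exactly
that model.  Note one subtlety: the matching conserves the sex totals, so
the four counts satisfy two linear constraints and the classical
``chi2(df=3)`` reference distribution for the Pearson statistic is
conservative under it; the Monte-Carlo p-value is exact up to simulation
error.  See the package methods note for the calibration analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "COMBINATIONS",
    "SexedPool",
    "PairCountTable",
    "ExpectedPairFrequencies",
    "GofResult",
    "MonteCarloNull",
    "ExactNull",
    "PreferenceEstimate",
    "derive_pool",
    "expected_random_pairing",
    "chi_squared_gof",
    "monte_carlo_null",
    "exact_enumeration",
    "preference_estimate",
]

#: Ordered sex-combination keys; XY = role-1 sex X, role-2 sex Y.
COMBINATIONS: tuple[str, ...] = ("FM", "MM", "MF", "FF")

#: Role-label pairs by association type (role 1 first).
ROLE_LABELS: dict[str, tuple[str, str]] = {
    "trail_following": ("marker", "tracker"),
    "tower": ("bottom", "top"),
}

EXACT_ENUMERATION_CAP = 12  # individuals; (cap-1)!! matchings is still cheap


@dataclass(frozen=True)
class SexedPool:
    """Pool of sexed individuals available for pairing.

    Parameters
    ----------
    males, females
        Non-negative counts; at least two individuals in total.
    """

    males: int
    females: int

    def __post_init__(self) -> None:
        if self.males < 0 or self.females < 0:
            raise ValueError("pool counts must be non-negative")
        if self.total < 2:
            raise ValueError("pool must contain at least two individuals")

    @property
    def total(self) -> int:
        return self.males + self.females

    @property
    def n_pairs(self) -> int:
        """Number of complete pairs the pool supports (total must be even)."""
        if self.total % 2:
            raise ValueError("pool has an odd number of individuals")
        return self.total // 2


@dataclass
class PairCountTable:
    """Observed counts of the four ordered sex combinations for one table.

    ``counts`` maps each key in :data:`COMBINATIONS` to a non-negative
    integer.  ``inferred`` lists keys whose counts were not given directly
    but reconstructed from a declared total (flagged, never silent).
    """

    counts: dict[str, int]
    association_type: str = "trail_following"
    species: str = ""
    tide_phase: str = ""
    inferred: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(COMBINATIONS)
        if unknown:
            raise ValueError(f"unknown combination keys: {sorted(unknown)}")
        missing = set(COMBINATIONS) - set(self.counts)
        if missing:
            raise ValueError(f"missing combination counts: {sorted(missing)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("combination counts must be non-negative")
        if self.n_pairs < 1:
            raise ValueError("table must contain at least one pair")
        if self.association_type not in ROLE_LABELS:
            raise ValueError(
                f"association_type must be one of {sorted(ROLE_LABELS)}"
            )

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def role_labels(self) -> tuple[str, str]:
        return ROLE_LABELS[self.association_type]

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[k] for k in COMBINATIONS], dtype=float)


@dataclass(frozen=True)
class ExpectedPairFrequencies:
    """Expected combination counts under random pairing from a finite pool."""

    expected: Mapping[str, float]
    pool: SexedPool
    n_pairs: int

    def as_array(self) -> np.ndarray:
        return np.array([self.expected[k] for k in COMBINATIONS], dtype=float)


@dataclass
class GofResult:
    """Goodness-of-fit of observed pair counts against the random-pairing null.

    ``chi2`` is the Pearson statistic over retained categories (those with
    positive expectation), ``df`` = retained − 1.  ``method`` records how
    the p-value was obtained: ``"analytic"`` (chi-square upper tail at
    ``df``) or ``"monte_carlo"`` (rank against simulated matchings).
    """

    chi2: float
    df: int
    p_value: float
    expected: ExpectedPairFrequencies
    observed: PairCountTable
    method: str = "analytic"
    warnings: list[str] = field(default_factory=list)
    retained: tuple[str, ...] = COMBINATIONS

    @property
    def p_annotation(self) -> str:
        """Significance annotation in the conventional reporting style."""
        if self.p_value < 0.001:
            return "< .001"
        if self.p_value < 0.05:
            return "< .05"
        return "n.s."

    def to_dict(self) -> dict:
        """Tidy, report-ready mapping (expecteds 1 dp, chi2 2 dp)."""
        return {
            "association_type": self.observed.association_type,
            "species": self.observed.species,
            "tide_phase": self.observed.tide_phase,
            "n_pairs": self.observed.n_pairs,
            "observed": dict(self.observed.counts),
            "expected": {
                k: round(v, 1) for k, v in self.expected.expected.items()
            },
            "chi2": round(self.chi2, 2),
            "df": self.df,
            "p_value": self.p_value,
            "p_annotation": self.p_annotation,
            "method": self.method,
            "warnings": list(self.warnings)
            + [f"count inferred from declared total: {k}"
               for k in self.observed.inferred],
        }


def derive_pool(counts: PairCountTable) -> SexedPool:
    """Recover the pool of individuals implied by a table of pair counts.

    Every MM pair contributes two males, every FF pair two females, and
    each mixed pair one of each, so ``m = 2·MM + FM + MF`` and
    ``n = 2·FF + FM + MF``.
    """
    c = counts.counts
    males = 2 * c["MM"] + c["FM"] + c["MF"]
    females = 2 * c["FF"] + c["FM"] + c["MF"]
    return SexedPool(males, females)


def expected_random_pairing(
    pool: SexedPool, n_pairs: int | None = None
) -> ExpectedPairFrequencies:
    """Expected combination counts if pairs form at random from ``pool``.

    Parameters
    ----------
    pool
        The available males and females; ``pool.total`` must equal
        ``2 * n_pairs``.
    n_pairs
        Number of pairs; defaults to ``pool.total // 2``.
    """
    if n_pairs is None:
        n_pairs = pool.n_pairs
    if pool.total != 2 * n_pairs:
        raise ValueError(
            f"pool of {pool.total} individuals is inconsistent with "
            f"{n_pairs} pairs"
        )
    m, n = float(pool.males), float(pool.females)
    denom = m + n - 1.0
    mixed = 0.5 * m * n / denom  # E[FM] = E[MF] exactly, by fair orientation
    expected = {
        "FM": mixed,
        "MM": m * 0.5 * ((m - 1.0) / denom),
        "MF": mixed,
        "FF": n * 0.5 * ((n - 1.0) / denom),
    }
    return ExpectedPairFrequencies(expected=expected, pool=pool, n_pairs=n_pairs)


def _pearson(observed: np.ndarray, expected: np.ndarray) -> float:
    return float(np.sum((observed - expected) ** 2 / expected))


def chi_squared_gof(
    observed: PairCountTable,
    expected: ExpectedPairFrequencies | None = None,
    *,
    method: str = "analytic",
    replicates: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> GofResult:
    """Pearson goodness-of-fit test of observed counts against the null.

    Categories with zero expectation (single-sex pools) are dropped and the
    degrees of freedom reduced accordingly; with all four categories
    retained ``df = 3``.  A warning is recorded whenever any retained
    expectation is below 5, the classical validity limit — the Monte-Carlo
    p-value (``method="monte_carlo"``) is then the safer choice.

    Parameters
    ----------
    observed
        The observed combination counts.
    expected
        Null expectations; derived from ``observed`` via
        :func:`derive_pool` when omitted.
    method
        ``"analytic"`` for the chi-square upper-tail p-value, or
        ``"monte_carlo"`` for a p-value ranked against simulated uniform
        matchings (requires ``seed``).
    """
    if expected is None:
        expected = expected_random_pairing(derive_pool(counts=observed))
    if set(expected.expected) != set(COMBINATIONS):
        raise ValueError("expected categories do not match the observed table")
    if expected.n_pairs != observed.n_pairs:
        raise ValueError("expected and observed tables disagree on N")

    obs = observed.as_array()
    exp = expected.as_array()
    warnings: list[str] = []

    keep = exp > 0
    if not keep.any():
        raise ValueError("all expected counts are zero")
    if (obs[~keep] > 0).any():
        raise ValueError("observed count positive in a zero-expectation category")
    retained = tuple(k for k, kept in zip(COMBINATIONS, keep) if kept)
    if len(retained) < 4:
        dropped = sorted(set(COMBINATIONS) - set(retained))
        warnings.append(f"dropped zero-expectation categories: {dropped}")
    if (exp[keep] < 5).any():
        low = [k for k, e in zip(COMBINATIONS, exp) if 0 < e < 5]
        warnings.append(
            f"expected count below 5 for {low}; "
            "consider the Monte-Carlo p-value"
        )

    chi2 = _pearson(obs[keep], exp[keep])
    df = int(keep.sum()) - 1

    if method == "analytic":
        p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    elif method == "monte_carlo":
        if seed is None:
            raise ValueError("monte_carlo method requires a seed")
        null = monte_carlo_null(
            expected.pool, expected.n_pairs, replicates=replicates, seed=seed
        )
        p_value = null.p_value_for(chi2)
    else:
        raise ValueError(f"unknown method {method!r}")

    return GofResult(
        chi2=chi2,
        df=df,
        p_value=p_value,
        expected=expected,
        observed=observed,
        method=method,
        warnings=warnings,
        retained=retained,
    )


@dataclass
class MonteCarloNull:
    """Empirical null distribution from simulated uniform matchings.

    ``counts`` holds one row per replicate in :data:`COMBINATIONS` order;
    ``chi2_samples`` the Pearson statistic of each replicate against the
    analytic expectations.
    """

    pool: SexedPool
    n_pairs: int
    counts: np.ndarray
    chi2_samples: np.ndarray
    expected: ExpectedPairFrequencies

    @property
    def mean_counts(self) -> dict[str, float]:
        return dict(zip(COMBINATIONS, self.counts.mean(axis=0)))

    @property
    def se_counts(self) -> dict[str, float]:
        r = self.counts.shape[0]
        return dict(zip(COMBINATIONS, self.counts.std(axis=0, ddof=1) / math.sqrt(r)))

    def p_value_for(self, chi2_observed: float) -> float:
        """Add-one Monte-Carlo p-value for an observed statistic."""
        r = len(self.chi2_samples)
        exceed = int(np.sum(self.chi2_samples >= chi2_observed - 1e-12))
        return (1 + exceed) / (1 + r)

    def critical_value(self, alpha: float = 0.05) -> float:
        """Statistic threshold whose MC p-value falls below ``alpha``."""
        return float(np.quantile(self.chi2_samples, 1.0 - alpha))


def monte_carlo_null(
    pool: SexedPool,
    n_pairs: int | None = None,
    *,
    replicates: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> MonteCarloNull:
    """Simulate the matching null: uniform perfect matching + fair orientation.

    Each replicate permutes the ``m + n`` individuals uniformly, pairs
    them off consecutively (a uniform perfect matching), and assigns the
    role-1/role-2 orientation of each pair by an independent fair coin.
    Reproducible for a fixed ``seed``.
    """
    if seed is None:
        raise ValueError("monte_carlo_null requires a seed for reproducibility")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if n_pairs is None:
        n_pairs = pool.n_pairs
    if pool.total != 2 * n_pairs:
        raise ValueError("pool size must equal twice the number of pairs")
    rng = np.random.default_rng(seed)

    sexes = np.concatenate(
        [np.ones(pool.males, dtype=np.int8), np.zeros(pool.females, dtype=np.int8)]
    )  # 1 = male
    expected = expected_random_pairing(pool, n_pairs)
    exp = expected.as_array()
    keep = exp > 0

    counts = np.empty((replicates, 4), dtype=np.int64)
    for r in range(replicates):
        perm = rng.permutation(sexes)
        a, b = perm[0::2], perm[1::2]
        swap = rng.random(n_pairs) < 0.5
        role1 = np.where(swap, b, a)
        role2 = np.where(swap, a, b)
        counts[r, 0] = np.sum((role1 == 0) & (role2 == 1))  # FM
        counts[r, 1] = np.sum((role1 == 1) & (role2 == 1))  # MM
        counts[r, 2] = np.sum((role1 == 1) & (role2 == 0))  # MF
        counts[r, 3] = np.sum((role1 == 0) & (role2 == 0))  # FF

    dev = counts[:, keep] - exp[keep]
    chi2_samples = np.sum(dev**2 / exp[keep], axis=1)
    return MonteCarloNull(
        pool=pool,
        n_pairs=n_pairs,
        counts=counts,
        chi2_samples=chi2_samples,
        expected=expected,
    )


@dataclass(frozen=True)
class ExactNull:
    """Exact combination-count distribution under the matching null.

    ``distribution`` maps count tuples in :data:`COMBINATIONS` order to
    probabilities summing to one.
    """

    pool: SexedPool
    distribution: Mapping[tuple[int, int, int, int], float]

    @property
    def expected(self) -> dict[str, float]:
        exp = np.zeros(4)
        for counts, p in self.distribution.items():
            exp += p * np.asarray(counts)
        return dict(zip(COMBINATIONS, exp))


def _matchings(individuals: Sequence[int]) -> Iterable[tuple[tuple[int, int], ...]]:
    """All perfect matchings of a sequence of sexes (1 = male), as pair tuples."""
    if not individuals:
        yield ()
        return
    first, rest = individuals[0], list(individuals[1:])
    for i in range(len(rest)):
        partner = rest[i]
        remainder = rest[:i] + rest[i + 1 :]
        for sub in _matchings(remainder):
            yield ((first, partner),) + sub


def exact_enumeration(pool: SexedPool, cap: int = EXACT_ENUMERATION_CAP) -> ExactNull:
    """Brute-force null distribution by enumerating matchings × orientations.

    Every perfect matching of the ``m + n`` labeled individuals is
    enumerated with equal weight, and every pair orientation within each
    matching with weight ``2^-N``.  Feasible for small pools only
    (``(m+n-1)!! * 2^N`` outcomes); serves as the independent oracle for
    :func:`expected_random_pairing` and :func:`monte_carlo_null`.
    """
    if pool.total % 2:
        raise ValueError("pool has an odd number of individuals")
    if pool.total > cap:
        raise ValueError(f"pool of {pool.total} exceeds enumeration cap {cap}")
    individuals = [1] * pool.males + [0] * pool.females
    n_pairs = pool.total // 2

    dist: dict[tuple[int, int, int, int], float] = {}
    n_matchings = 0
    for matching in _matchings(individuals):
        n_matchings += 1
        for orient in itertools.product((0, 1), repeat=n_pairs):
            key = [0, 0, 0, 0]  # FM MM MF FF
            for (a, b), flip in zip(matching, orient):
                r1, r2 = (b, a) if flip else (a, b)
                if r1 == 0 and r2 == 1:
                    key[0] += 1
                elif r1 == 1 and r2 == 1:
                    key[1] += 1
                elif r1 == 1 and r2 == 0:
                    key[2] += 1
                else:
                    key[3] += 1
            dist[tuple(key)] = dist.get(tuple(key), 0) + 1
    weight = 1.0 / (n_matchings * 2**n_pairs)
    return ExactNull(
        pool=pool, distribution={k: v * weight for k, v in dist.items()}
    )


@dataclass(frozen=True)
class PreferenceEstimate:
    """Moment estimate of the directed-preference strength θ.

    θ is the probability that a pair forms as a directed female-marker →
    male-tracker event rather than by random pairing (the generator model
    in :mod:`highshore.simulate`); θ = 0 is the null.  The estimator is
    the excess of observed FM pairs over the null expectation, scaled by
    the maximum possible excess, clipped to [0, 1].
    """

    theta_hat: float
    expected_fm: float
    observed_fm: int
    n_pairs: int
    clipped: bool


def preference_estimate(
    observed: PairCountTable,
    expected: ExpectedPairFrequencies | None = None,
) -> PreferenceEstimate:
    """Plug-in estimate θ̂ = (O_FM − E_FM) / (N − E_FM), clipped to [0, 1]."""
    if expected is None:
        expected = expected_random_pairing(derive_pool(observed))
    pool = expected.pool
    if pool.males == 0 or pool.females == 0:
        raise ValueError("preference is undefined for a single-sex pool")
    e_fm = expected.expected["FM"]
    n_pairs = observed.n_pairs
    if n_pairs <= e_fm:
        raise ValueError("N must exceed the null FM expectation")
    raw = (observed.counts["FM"] - e_fm) / (n_pairs - e_fm)
    theta = min(1.0, max(0.0, raw))
    return PreferenceEstimate(
        theta_hat=theta,
        expected_fm=e_fm,
        observed_fm=observed.counts["FM"],
        n_pairs=n_pairs,
        clipped=theta != raw,
    )
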