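"""Global test of association between a response profile and covariate profiles.

The statistic is the linear-model score form of the global test.  With the
centered response r = y - mean(y), standardized covariate columns x_j and
s^2 = r'r / n, each covariate contributes

    c_j = (x_j' r)^2 / (m s^2),        Q = sum_j c_j,

so Q is large when at least one covariate profile is (anti-)correlated with
the response.  The null hypothesis — no covariate is associated with the
response — is exchangeable in the response values, so p-values come from
the permutation distribution of Q: exhaustive enumeration for small n,
seeded Monte-Carlo permutation by default, or a moment-matched gamma tail
as a fast approximation.  Per-covariate contributions carry the sign of the
centered cross-product, i.e. the direction of the marginal association.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import Assay, DEFAULT_MIN_SAMPLES

log = logging.getLogger(__name__)

EXHAUSTIVE_MAX_N = 9
MIN_PERMUTATIONS = 999


class UntestableError(ValueError):
    """The pair/group cannot be tested (constant profile or too few samples)."""


class Sign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    ZERO = "zero"


class Transform(str, Enum):
    LOG2P1 = "log2p1"
    NONE = "none"


#: Default per-assay expression transform: FPKM-like assays are log2(v+1)
#: compressed; protein intensities are already normalized and left alone.
DEFAULT_TRANSFORMS = {
    Assay.MIRNA: Transform.LOG2P1,
    Assay.GENE: Transform.LOG2P1,
    Assay.PROTEIN: Transform.NONE,
}


def apply_transform(values: np.ndarray, transform: Transform | str) -> np.ndarray:
    transform = Transform(transform)
    if transform is Transform.LOG2P1:
        return np.log2(np.asarray(values, dtype=float) + 1.0)
    return np.asarray(values, dtype=float)


@dataclass(frozen=True)
class GlobalTestConfig:
    """Configuration shared by all association tests in a run.

    method "auto" uses exhaustive enumeration when n <= 9 and seeded
    permutation otherwise; "gamma" is an opt-in fast approximation.
    """

    method: str = "auto"  # auto | permutation | exhaustive | gamma
    n_perm: int = 10_000
    seed: int = 0
    standardize: bool = True
    min_samples: int = DEFAULT_MIN_SAMPLES


@dataclass
class GlobalTestInput:
    """A response vector and covariate matrix over the same ordered samples."""

    y: np.ndarray
    X: np.ndarray  # n x m
    covariate_ids: list[str] | None = None
    response_id: str = "response"
    transform: Transform = Transform.NONE
    standardize: bool = True
    min_samples: int = DEFAULT_MIN_SAMPLES

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("y and X must share the sample dimension")
        if self.X.shape[1] < 1:
            raise ValueError("at least one covariate is required")
        if self.covariate_ids is None:
            self.covariate_ids = [f"x{j}" for j in range(self.X.shape[1])]
        if len(self.covariate_ids) != self.X.shape[1]:
            raise ValueError("covariate_ids length must equal the number of columns")

    def prepare(self) -> "PreparedInput":
        """Transform, complete-case filter, center and (optionally) standardize."""
        y = apply_transform(self.y, self.transform)
        X = apply_transform(self.X, self.transform)
        keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
        n_dropped = int((~keep).sum())
        y, X = y[keep], X[keep]
        n = y.shape[0]
        if n < self.min_samples:
            raise UntestableError(
                f"{self.response_id}: only {n} complete cases "
                f"(min_samples={self.min_samples})"
            )
        r = y - y.mean()
        s2 = float(r @ r) / n
        if s2 == 0.0:
            raise UntestableError(f"constant response profile {self.response_id!r}")
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0)
        const = np.flatnonzero(sd == 0.0)
        if const.size:
            raise UntestableError(
                f"constant covariate profile {self.covariate_ids[const[0]]!r}"
            )
        Xs = Xc / sd if self.standardize else Xc
        return PreparedInput(
            r=r, Xs=Xs, s2=s2, n_dropped=n_dropped,
            covariate_ids=list(self.covariate_ids),
        )


@dataclass
class PreparedInput:
    r: np.ndarray  # centered response
    Xs: np.ndarray  # centered (standardized) covariates, n x m
    s2: float  # r'r / n
    n_dropped: int
    covariate_ids: list[str]

    @property
    def n(self) -> int:
        return self.r.shape[0]

    @property
    def m(self) -> int:
        return self.Xs.shape[1]


@dataclass
class CovariateContribution:
    covariate_id: str
    contribution: float
    sign: Sign


@dataclass
class GlobalTestResult:
    statistic: float
    p_value: float
    method: str
    n_used: int
    m: int
    n_perm: int | None = None
    seed: int | None = None
    n_dropped: int = 0


@dataclass
class PairAssociation:
    """p-value + direction of one (response, covariate) profile association."""

    response_id: str
    covariate_id: str
    p_value: float | None
    sign: Sign
    n_used: int
    statistic: float | None = None
    method: str | None = None
    untestable: bool = False
    reason: str = ""

    @property
    def testable(self) -> bool:
        return not self.untestable and self.p_value is not None


def _sign_of(value: float) -> Sign:
    if value > 0:
        return Sign.POSITIVE
    if value < 0:
        return Sign.NEGATIVE
    return Sign.ZERO


def _statistic_from_prepared(prep: PreparedInput) -> tuple[float, list[CovariateContribution]]:
    cross = prep.Xs.T @ prep.r  # length m
    contrib = cross**2 / (prep.m * prep.s2)
    contributions = [
        CovariateContribution(cid, float(c), _sign_of(float(x)))
        for cid, c, x in zip(prep.covariate_ids, contrib, cross)
    ]
    return float(contrib.sum()), contributions


def global_statistic(inp: GlobalTestInput) -> tuple[float, list[CovariateContribution]]:
    """Compute Q and the per-covariate decomposition (sums to Q)."""
    return _statistic_from_prepared(inp.prepare())


def _null_statistics(prep: PreparedInput, perm_rows: np.ndarray) -> np.ndarray:
    """Q for each row of ``perm_rows`` (each a permutation of 0..n-1)."""
    R = prep.r[perm_rows]  # B x n
    S = R @ prep.Xs  # B x m
    return (S**2).sum(axis=1) / (prep.m * prep.s2)


def _tie_threshold(q_obs: float) -> float:
    """Count null statistics within 1e-9 relative of the observed value as
    ties (>=): exactly tied rearrangements (common for integer-valued data)
    would otherwise be kept or dropped by last-ulp rounding accidents."""
    return q_obs - 1e-9 * max(abs(q_obs), 1e-300)


def p_value_exhaustive(inp: GlobalTestInput) -> GlobalTestResult:
    """Exact permutation p over all n! rearrangements of the response (n <= 9)."""
    prep = inp.prepare()
    if prep.n > EXHAUSTIVE_MAX_N:
        raise ValueError(
            f"n={prep.n} is too large for exhaustive enumeration "
            f"(max {EXHAUSTIVE_MAX_N}); use the permutation method"
        )
    perms = np.array(list(itertools.permutations(range(prep.n))), dtype=np.intp)
    q_null = _null_statistics(prep, perms)
    # itertools yields the identity first; taking the observed statistic from
    # the same batched computation guarantees it counts itself (different
    # BLAS code paths can otherwise disagree by 1 ulp).
    q_obs = float(q_null[0])
    p = float(np.count_nonzero(q_null >= _tie_threshold(q_obs))) / perms.shape[0]
    return GlobalTestResult(
        statistic=q_obs, p_value=p, method="exhaustive",
        n_used=prep.n, m=prep.m, n_dropped=prep.n_dropped,
    )


def p_value_permutation(
    inp: GlobalTestInput, n_perm: int = 10_000, seed: int = 0
) -> GlobalTestResult:
    """Seeded Monte-Carlo permutation p with the (b+1)/(B+1) floor."""
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")
    prep = inp.prepare()
    rng = np.random.default_rng(seed)
    rows = np.tile(np.arange(prep.n, dtype=np.intp), (n_perm + 1, 1))
    rng.permuted(rows[1:], axis=1, out=rows[1:])
    # Row 0 stays the identity: evaluating the observed statistic inside the
    # same batch keeps it bit-consistent with the null statistics.
    q_all = _null_statistics(prep, rows)
    q_obs = float(q_all[0])
    q_null = q_all[1:]
    b = int(np.count_nonzero(q_null >= _tie_threshold(q_obs)))
    p = (b + 1) / (n_perm + 1)
    return GlobalTestResult(
        statistic=q_obs, p_value=p, method="permutation",
        n_used=prep.n, m=prep.m, n_perm=n_perm, seed=seed,
        n_dropped=prep.n_dropped,
    )


def permutation_null_moments(prep: PreparedInput) -> tuple[float, float]:
    """Exact mean and variance of Q under uniform permutation of the response.

    Q(pi) = r_pi' A r_pi with A = Xs Xs' / (m s^2).  Because the covariate
    columns are centered, A is doubly centered, and r sums to zero, so the
    permutation moments reduce to closed forms in tr(A), tr(A^2), the
    diagonal of A and the power sums of r.  Requires n >= 4.
    """
    n, m = prep.n, prep.m
    if n < 4:
        raise ValueError("permutation moments require n >= 4")
    c = 1.0 / (m * prep.s2)
    diag_a = (prep.Xs**2).sum(axis=1) * c
    d1 = float(diag_a.sum())  # tr(A)
    d2 = float((diag_a**2).sum())  # sum of squared diagonal
    gram = prep.Xs.T @ prep.Xs  # m x m
    f = float((gram**2).sum()) * c * c  # tr(A^2)
    r = prep.r
    b2 = float((r**2).sum())
    b4 = float((r**4).sum())

    mean = d1 * b2 / (n - 1)
    # E[Q^2] by index-coincidence pattern of the 4 positions (i,j,k,l):
    e_q2 = (
        d2 * b4 / n  # all four equal
        + 4.0 * d2 * b4 / (n * (n - 1))  # three equal
        + (d1**2 - d2 + 2.0 * (f - d2)) * (b2**2 - b4) / (n * (n - 1))  # two pairs
        + (-2.0 * d1**2 + 12.0 * d2 - 4.0 * f)
        * (2.0 * b4 - b2**2)
        / (n * (n - 1) * (n - 2))  # one pair + two singletons
        + (d1**2 + 2.0 * f - 6.0 * d2)
        * (3.0 * b2**2 - 6.0 * b4)
        / (n * (n - 1) * (n - 2) * (n - 3))  # all distinct
    )
    var = e_q2 - mean**2
    return mean, max(var, 0.0)


def p_value_gamma(inp: GlobalTestInput) -> GlobalTestResult:
    """Gamma tail matched to the first two permutation-null moments of Q."""
    prep = inp.prepare()
    q_obs, _ = _statistic_from_prepared(prep)
    if q_obs == 0.0:
        p = 1.0
    else:
        mean, var = permutation_null_moments(prep)
        if var <= 0.0:
            raise UntestableError("degenerate permutation null (zero variance)")
        shape = mean**2 / var
        scale = var / mean
        p = float(np.clip(stats.gamma.sf(q_obs, a=shape, scale=scale), 0.0, 1.0))
    return GlobalTestResult(
        statistic=q_obs, p_value=p, method="gamma",
        n_used=prep.n, m=prep.m, n_dropped=prep.n_dropped,
    )


def run_global_test(inp: GlobalTestInput, config: GlobalTestConfig, seed: int | None = None
                    ) -> tuple[GlobalTestResult, list[CovariateContribution]]:
    """Dispatch on the configured p-value method ("auto" picks by n)."""
    prep = inp.prepare()
    q_obs, contributions = _statistic_from_prepared(prep)
    method = config.method
    if method == "auto":
        method = "exhaustive" if prep.n <= EXHAUSTIVE_MAX_N else "permutation"
    if method == "exhaustive":
        result = p_value_exhaustive(inp)
    elif method == "permutation":
        result = p_value_permutation(
            inp, n_perm=config.n_perm, seed=config.seed if seed is None else seed
        )
    elif method == "gamma":
        result = p_value_gamma(inp)
    else:
        raise ValueError(f"unknown p-value method {config.method!r}")
    return result, contributions


def pair_association(
    y_profile: pd.Series | np.ndarray,
    x_profile: pd.Series | np.ndarray,
    *,
    response_id: str,
    covariate_id: str,
    response_transform: Transform | str = Transform.LOG2P1,
    covariate_transform: Transform | str = Transform.LOG2P1,
    config: GlobalTestConfig = GlobalTestConfig(),
    seed: int | None = None,
) -> PairAssociation:
    """m=1 global test of one covariate profile against one response profile.

    Orientation follows the regulatory arrow: the downstream profile is the
    response (gene responds to miRNA, protein responds to gene).  Each
    profile gets its assay's transform before complete-case filtering; an
    untestable pair (constant profile, too few complete cases) is flagged
    rather than dropped.
    """
    y = np.asarray(y_profile, dtype=float).ravel()
    x = np.asarray(x_profile, dtype=float).ravel()
    if y.shape != x.shape:
        raise ValueError("profiles must cover the same ordered sample set")
    yt = apply_transform(y, response_transform)
    xt = apply_transform(x, covariate_transform)
    inp = GlobalTestInput(
        y=yt, X=xt[:, None], covariate_ids=[covariate_id],
        response_id=response_id, transform=Transform.NONE,
        standardize=config.standardize, min_samples=config.min_samples,
    )
    try:
        result, contributions = run_global_test(inp, config, seed=seed)
    except UntestableError as exc:
        keep = ~(np.isnan(yt) | np.isnan(xt))
        return PairAssociation(
            response_id=response_id, covariate_id=covariate_id,
            p_value=None, sign=Sign.ZERO, n_used=int(keep.sum()),
            untestable=True, reason=str(exc),
        )
    sign = contributions[0].sign
    if sign is Sign.ZERO:
        # exactly-zero cross-product: direction undefined, flagged untestable
        return PairAssociation(
            response_id=response_id, covariate_id=covariate_id,
            p_value=None, sign=Sign.ZERO, n_used=result.n_used,
            statistic=result.statistic, method=result.method,
            untestable=True, reason="zero centered cross-product",
        )
    return PairAssociation(
        response_id=response_id, covariate_id=covariate_id,
        p_value=result.p_value, sign=sign, n_used=result.n_used,
        statistic=result.statistic, method=result.method,
    )


def group_target_test(
    mirna_profile: pd.Series | np.ndarray,
    target_matrix: pd.DataFrame,
    *,
    mirna_id: str = "mirna",
    response_transform: Transform | str = Transform.LOG2P1,
    target_transform: Transform | str = Transform.LOG2P1,
    config: GlobalTestConfig = GlobalTestConfig(),
    seed: int | None = None,
) -> tuple[GlobalTestResult, list[CovariateContribution]]:
    """Test a miRNA profile against the group of its target-gene profiles.

    The miRNA is the response and the targets are the covariates (the group
    orientation); contributions are returned with the strongest
    anti-correlated targets first, since anti-correlation is the signature
    of genuine targeting.  Constant target profiles are excluded (logged);
    if none remain the group is untestable.
    """
    y = apply_transform(np.asarray(mirna_profile, dtype=float).ravel(), response_transform)
    X = apply_transform(target_matrix.to_numpy(dtype=float).T, target_transform)
    ids = [str(i) for i in target_matrix.index]
    if X.shape[0] != y.shape[0]:
        raise ValueError("targets must cover the same ordered sample set")
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    sd = X[keep].std(axis=0)
    usable = np.flatnonzero(sd > 0.0)
    if usable.size == 0:
        raise UntestableError(f"all target profiles for {mirna_id!r} are constant")
    if usable.size < len(ids):
        dropped = [ids[j] for j in range(len(ids)) if j not in set(usable.tolist())]
        log.info("group test %s: excluded constant targets %s", mirna_id, dropped)
    inp = GlobalTestInput(
        y=y, X=X[:, usable], covariate_ids=[ids[j] for j in usable],
        response_id=mirna_id, transform=Transform.NONE,
        standardize=config.standardize, min_samples=config.min_samples,
    )
    result, contributions = run_global_test(inp, config, seed=seed)
    contributions.sort(
        key=lambda c: (0 if c.sign is Sign.NEGATIVE else 1, -c.contribution)
    )
    return result, contributions
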