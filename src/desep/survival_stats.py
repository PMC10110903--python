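"""Censored-survival statistics used to evaluate prognostic groupings.

Everything here is implemented from first principles (product-limit
estimator, log-rank, binary-covariate Cox partial likelihood with Breslow
tie handling, Harrell's concordance index, Cramér's phi) so that each
statistic can be checked against brute-force oracles on small instances.

Conventions
-----------
* ``time`` is years from the start of treatment, strictly positive.
* ``event`` is 1 for an observed event, 0 for right-censoring at ``time``.
* Two-sided alpha = 0.05 throughout; confidence intervals are 95% Wald.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time (years), event indicator, group or score."""

    time: float
    event: int
    group_or_score: float = 0.0

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table of two dichotomous categorizations."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self):
        counts = (self.n11, self.n12, self.n21, self.n22)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("table total must be >= 1")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    p: float
    monotone_likelihood: bool = False


def _as_arrays(records: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.asarray([r.time for r in records], dtype=float)
    e = np.asarray([r.event for r in records], dtype=int)
    g = np.asarray([r.group_or_score for r in records], dtype=float)
    return t, e, g


def km_curve(records: Sequence[SurvivalRecord]) -> list[tuple[float, float]]:
    """Kaplan-Meier product-limit estimate.

    Returns the right-continuous step function as ``[(t, S(t)), ...]`` over
    the distinct event times, prefixed with ``(0.0, 1.0)``.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    t, e, _ = _as_arrays(records)
    steps = [(0.0, 1.0)]
    s = 1.0
    for ti in np.unique(t[e == 1]):
        at_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d / at_risk
        steps.append((float(ti), s))
    return steps


def km_survival_at(records: Sequence[SurvivalRecord], horizon: float) -> float:
    """S(horizon) read off the Kaplan-Meier step function."""
    s = 1.0
    for ti, si in km_curve(records):
        if ti <= horizon:
            s = si
    return s


def restricted_mean_survival(records: Sequence[SurvivalRecord],
                             tau: float | None = None) -> float:
    """Area under the KM curve up to ``tau`` (default: last observed time)."""
    t, _, _ = _as_arrays(records)
    if tau is None:
        tau = float(t.max())
    steps = km_curve(records) + [(tau, np.nan)]
    area = 0.0
    for (t0, s0), (t1, _) in zip(steps[:-1], steps[1:]):
        lo, hi = min(t0, tau), min(t1, tau)
        area += s0 * max(0.0, hi - lo)
    return area


def logrank(records_a: Sequence[SurvivalRecord],
            records_b: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square, p from chi2 with 1 df).

    Observed-minus-expected events in group A accumulated over distinct
    event times, with the hypergeometric variance at each time.
    """
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both groups must be nonempty")
    ta, ea, _ = _as_arrays(records_a)
    tb, eb, _ = _as_arrays(records_b)
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for ti in times:
        na = np.sum(ta >= ti)
        nb = np.sum(tb >= ti)
        da = np.sum((ta == ti) & (ea == 1))
        db = np.sum((tb == ti) & (eb == 1))
        n = na + nb
        d = da + db
        if n < 2:
            continue
        exp_a = d * na / n
        v = d * (na / n) * (nb / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += da - exp_a
        var += v
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    p = float(_sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def _cox_negloglik_grad_hess(beta: float, t: np.ndarray, e: np.ndarray,
                             x: np.ndarray) -> tuple[float, float, float]:
    """Breslow partial log-likelihood, score, and information for one
    binary (or scalar) covariate."""
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    loglik = 0.0
    score = 0.0
    info = 0.0
    eta = np.exp(beta * x)
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        events = (t == ti) & (e == 1)
        d = int(events.sum())
        s0 = float(eta[at_risk].sum())
        s1 = float((eta[at_risk] * x[at_risk]).sum())
        s2 = float((eta[at_risk] * x[at_risk] ** 2).sum())
        sx = float(x[events].sum())
        loglik += beta * sx - d * np.log(s0)
        score += sx - d * s1 / s0
        info += d * (s2 / s0 - (s1 / s0) ** 2)
    return loglik, score, info


def cox_hr_binary(records: Sequence[SurvivalRecord],
                  max_iter: int = 100, tol: float = 1e-10) -> CoxResult:
    """Hazard ratio for a binary group covariate from Cox regression.

    Newton maximization of the Breslow partial likelihood; Wald 95% CI.
    A monotone likelihood (perfectly separated event ordering) is flagged
    and reported with an unbounded CI.
    """
    t, e, x = _as_arrays(records)
    if e.sum() == 0:
        raise ValueError("need at least one event")
    if np.unique(x).size < 2:
        raise ValueError("group covariate is constant")
    beta = 0.0
    for _ in range(max_iter):
        _, score, info = _cox_negloglik_grad_hess(beta, t, e, x)
        if info <= 0:
            break
        step = score / info
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(score) < tol:
            break
        if abs(beta) > 20:  # monotone likelihood: beta escapes to infinity
            _, _, info = _cox_negloglik_grad_hess(beta, t, e, x)
            return CoxResult(hr=float(np.exp(beta)), ci_low=0.0,
                             ci_high=np.inf, beta=beta, se=np.inf, p=1.0,
                             monotone_likelihood=True)
    _, score, info = _cox_negloglik_grad_hess(beta, t, e, x)
    se = float(np.sqrt(1.0 / info))
    z = beta / se
    p = float(2 * _sps.norm.sf(abs(z)))
    return CoxResult(hr=float(np.exp(beta)),
                     ci_low=float(np.exp(beta - 1.96 * se)),
                     ci_high=float(np.exp(beta + 1.96 * se)),
                     beta=float(beta), se=se, p=p)


def harrells_c(records: Sequence[SurvivalRecord]) -> float:
    """Harrell's concordance index for a continuous risk score.

    A pair is usable when the shorter follow-up ended in an event (or both
    are events at distinct times). The pair is concordant when the subject
    with the earlier event carries the higher risk score; tied scores count
    one half. Tied event times make the pair unusable.
    """
    t, e, s = _as_arrays(records)
    n = len(t)
    conc = 0.0
    usable = 0
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] == t[j]:
                continue  # tied times: unusable under Harrell's convention
            first, second = (i, j) if t[i] < t[j] else (j, i)
            if e[first] != 1:
                continue
            usable += 1
            if s[first] > s[second]:
                conc += 1.0
            elif s[first] == s[second]:
                conc += 0.5
    if usable == 0:
        raise ValueError("c undefined: no usable pairs")
    return conc / usable


def cramers_phi(table: TwoByTwo) -> tuple[float, float]:
    """Phi coefficient of a 2x2 table and its chi-square p-value.

    phi = (n11*n22 - n12*n21) / sqrt(r1*r2*c1*c2); chi2 = n*phi^2 on 1 df.
    """
    n11, n12, n21, n22 = table.n11, table.n12, table.n21, table.n22
    r1, r2 = n11 + n12, n21 + n22
    c1, c2 = n11 + n21, n12 + n22
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("phi undefined: zero margin")
    phi = (n11 * n22 - n12 * n21) / np.sqrt(float(r1) * r2 * c1 * c2)
    chi2 = table.total * phi ** 2
    p = float(_sps.chi2.sf(chi2, df=1))
    return float(phi), p


def bootstrap_c_se(records: Sequence[SurvivalRecord], n_boot: int = 200,
                   seed: int = 0) -> float:
    """Nonparametric bootstrap standard error of Harrell's c."""
    rng = np.random.default_rng(seed)
    records = list(records)
    n = len(records)
    cs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            cs.append(harrells_c([records[i] for i in idx]))
        except ValueError:
            continue
    if len(cs) < 2:
        return float("nan")
    return float(np.std(cs, ddof=1))
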