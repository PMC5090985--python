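"""Group comparison and methacholine dose-response analysis.

Scan summaries (one per animal and scan) are compared between groups --
healthy controls (CN), severe acute airway inflammation (SAA) and
dexamethasone-treated (SAA-DEX) -- with the unpaired Welch t-test, flagged at
p < 0.1 and p < 0.05.  Airway responsiveness is quantified as the per-animal
relative change of each parameter to its own baseline (0 mg/ml) across
increasing methacholine concentrations, with a per-dose Welch test against
the (identically zero) baseline changes.

No multiple-testing correction is applied by default; Holm correction is
available behind a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .breath_analysis import ScanSummary

#: mapping from user-facing parameter names to ScanSummary attributes
PARAM_ATTRS: dict[str, str] = {
    "b1": "mean_b1",
    "b2": "mean_b2",
    "b3": "mean_b3",
    "b4": "mean_b4",
    "b5": "mean_b5",
    "t_in": "mean_t_in_pct",
    "t_in_pct": "mean_t_in_pct",
    "bpm": "bpm",
    "max_slope": "max_slope",
    "min_slope": "min_slope",
    "peak_amplitude": "peak_amplitude",
}

DEFAULT_PARAMS = ("b1", "b2", "b3", "b4", "b5", "t_in")


class GroupTooSmallError(ValueError):
    """A group with fewer than two summaries cannot be tested."""


class UnknownParameterError(KeyError):
    """Requested parameter is not a known scan-summary field."""


@dataclass
class TestResult:
    """Welch t-test outcome with significance flags at the 0.1/0.05 margins."""

    t_stat: float
    dof: float
    p_value: float
    sig_010: bool = field(init=False)
    sig_005: bool = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        self.sig_010 = self.p_value < 0.1
        self.sig_005 = self.p_value < 0.05


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    results: dict[str, TestResult]
    means: dict[str, tuple[float, float]]  # per parameter: (mean_a, mean_b)
    sds: dict[str, tuple[float, float]]


@dataclass
class DoseResponseTable:
    """Per-animal relative changes (%) to baseline, per dose and parameter.

    ``rel_change[param]`` has shape (n_doses, n_animals); the first row (the
    baseline dose) is identically zero.  ``tests[param]`` holds one
    :class:`TestResult` per nonzero dose (change vs the zero-change baseline).
    """

    doses: tuple[float, ...]
    params: tuple[str, ...]
    rel_change: dict[str, np.ndarray]
    tests: dict[str, list[TestResult]]


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Unpaired two-sided Welch t-test for equal means.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with Welch-Satterthwaite
    degrees of freedom.  Degenerate conventions when both sample variances are
    zero: equal means give p = 1, different means give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise GroupTooSmallError(f"need n >= 2 per sample, got {na} and {nb}")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        dof = float(na + nb - 2)
        if ma == mb:
            return TestResult(t_stat=0.0, dof=dof, p_value=1.0)
        return TestResult(t_stat=np.inf if ma > mb else -np.inf, dof=dof, p_value=0.0)
    se2a, se2b = va / na, vb / nb
    t = (ma - mb) / np.sqrt(se2a + se2b)
    dof = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    return TestResult(t_stat=float(t), dof=float(dof), p_value=min(p, 1.0))


def _extract(summaries: Sequence[ScanSummary], param: str) -> np.ndarray:
    try:
        attr = PARAM_ATTRS[param]
    except KeyError as exc:
        raise UnknownParameterError(f"unknown parameter {param!r}") from exc
    return np.array([getattr(s, attr) for s in summaries], dtype=float)


def _holm_adjust(pvals: Sequence[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def compare_groups(
    groups: Mapping[str, Sequence[ScanSummary]],
    params: Sequence[str] = DEFAULT_PARAMS,
    holm: bool = False,
) -> list[GroupComparison]:
    """Pairwise Welch tests per parameter for every pair of named groups.

    Groups are compared in their given order (e.g. CN vs SAA, CN vs SAA-DEX,
    SAA vs SAA-DEX).  ``holm=True`` replaces the raw p-values by Holm
    step-down adjusted ones within each pairwise comparison.
    """
    for name, summaries in groups.items():
        if len(summaries) < 2:
            raise GroupTooSmallError(f"group {name!r} has fewer than 2 summaries")
    comparisons: list[GroupComparison] = []
    for (name_a, sum_a), (name_b, sum_b) in itertools.combinations(groups.items(), 2):
        results: dict[str, TestResult] = {}
        means: dict[str, tuple[float, float]] = {}
        sds: dict[str, tuple[float, float]] = {}
        for param in params:
            xa, xb = _extract(sum_a, param), _extract(sum_b, param)
            results[param] = welch_t_test(xa, xb)
            means[param] = (float(xa.mean()), float(xb.mean()))
            sds[param] = (float(xa.std(ddof=1)), float(xb.std(ddof=1)))
        if holm:
            adjusted = _holm_adjust([results[p].p_value for p in params])
            for param, p_adj in zip(params, adjusted):
                r = results[param]
                results[param] = TestResult(t_stat=r.t_stat, dof=r.dof, p_value=p_adj)
        comparisons.append(
            GroupComparison(
                group_a=name_a,
                group_b=name_b,
                n_a=len(sum_a),
                n_b=len(sum_b),
                results=results,
                means=means,
                sds=sds,
            )
        )
    return comparisons


def dose_response(
    per_dose_summaries: Sequence[Sequence[ScanSummary]],
    doses: Sequence[float],
    params: Sequence[str] = DEFAULT_PARAMS,
) -> DoseResponseTable:
    """Relative change to baseline per animal, parameter and dose.

    The first dose must be the 0 mg/ml baseline and animal counts must match
    across doses (animals are paired by position: each animal serves as its
    own baseline).  Relative change = 100 * (v - v0) / v0.  Per nonzero dose
    the changes are Welch-tested against the identically-zero baseline
    changes.
    """
    if len(per_dose_summaries) != len(doses):
        raise ValueError("one summary list per dose required")
    if not doses or doses[0] != 0:
        raise ValueError("first dose must be the 0 mg/ml baseline")
    if any(doses[i] >= doses[i + 1] for i in range(len(doses) - 1)):
        raise ValueError("doses must be strictly increasing")
    n_animals = len(per_dose_summaries[0])
    if n_animals < 2:
        raise GroupTooSmallError("need at least 2 animals")
    if any(len(s) != n_animals for s in per_dose_summaries):
        raise ValueError("equal animal counts required across doses (paired by animal)")

    rel_change: dict[str, np.ndarray] = {}
    tests: dict[str, list[TestResult]] = {}
    for param in params:
        values = np.array([_extract(s, param) for s in per_dose_summaries])  # doses x animals
        v0 = values[0]
        if np.any(v0 == 0.0):
            raise ValueError(f"baseline value is zero for parameter {param!r}")
        rel = 100.0 * (values - v0) / v0
        rel[0] = 0.0
        rel_change[param] = rel
        zeros = np.zeros(n_animals)
        tests[param] = [welch_t_test(rel[i], zeros) for i in range(1, len(doses))]
    return DoseResponseTable(
        doses=tuple(float(d) for d in doses),
        params=tuple(params),
        rel_change=rel_change,
        tests=tests,
    )
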