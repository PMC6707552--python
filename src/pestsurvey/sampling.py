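"""Acceptance-sampling expectations for a single survey site.

A survey site is treated as a lot in an acceptance-sampling plan: the host
trees are the items, a sample of ``n`` of the ``N`` trees is inspected, and
the site is declared infested as soon as one inspected tree tests positive.
Each tree is infested independently with probability ``gamma`` and an
inspection of an infested tree detects the infestation with probability
``e`` (the detection rate of the survey method).

The closed forms implemented here are

* the non-detection probability ``P = (1 - gamma*e)**n``,
* the sample adjustment factor ``beta = (1 - e) / (1 - gamma*e)``,
* the expected slippage ``E`` — infested trees left behind when the survey
  declares the site clean (or no survey happens),
* the expected detected-infested count ``F`` — infested trees present when
  the survey raises a detection, and
* the post-removal residual, where fractions ``y1`` (sampled population) and
  ``y2`` (unsampled population) of trees are removed after a detection.

``E + F == gamma * N`` always: splitting on the detection event cannot
change the unconditional expectation.

All functions broadcast over NumPy arrays; powers are evaluated through
``exp(n * log1p(-gamma*e))`` so that large sample sizes cannot underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SiteSamplingInputs",
    "SlippageDecomposition",
    "RemovalFractions",
    "prob_nondetection",
    "slippage_adjustment",
    "expected_slippage",
    "expected_detected_infested",
    "residual_after_removal",
    "decompose",
    "nondetection_prob_array",
    "pbeta_array",
]


def _check_unit(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1]; got {value!r}")


def _check_sample(n, N) -> None:
    n_arr = np.asarray(n)
    N_arr = np.asarray(N)
    if not np.issubdtype(n_arr.dtype, np.integer) and not np.all(
        np.equal(np.mod(n_arr, 1), 0)
    ):
        raise ValueError(f"sample size n must be integral; got {n!r}")
    if not np.issubdtype(N_arr.dtype, np.integer) and not np.all(
        np.equal(np.mod(N_arr, 1), 0)
    ):
        raise ValueError(f"population N must be integral; got {N!r}")
    if np.any(n_arr < 0):
        raise ValueError(f"sample size n must be >= 0; got {n!r}")
    if np.any(N_arr < 0):
        raise ValueError(f"population N must be >= 0; got {N!r}")
    if np.any(n_arr > N_arr):
        raise ValueError(f"sample size n={n!r} exceeds population N={N!r}")


@dataclass(frozen=True)
class SiteSamplingInputs:
    """Per-site sampling-plan inputs.

    Parameters
    ----------
    gamma : float
        Probability that a given tree at the site is infested, in [0, 1].
    e : float
        Detection rate: probability that inspecting one infested tree
        reveals the infestation, in [0, 1].
    n : int
        Number of trees inspected, ``0 <= n <= N``.
    N : int
        Number of host trees at the site.
    """

    gamma: float
    e: float
    n: int
    N: int

    def __post_init__(self) -> None:
        _check_unit("gamma", self.gamma)
        _check_unit("e", self.e)
        _check_sample(self.n, self.N)


@dataclass(frozen=True)
class RemovalFractions:
    """Fractions of trees removed after a detection.

    ``y1`` applies to the sampled population of ``n`` inspected trees and
    ``y2`` to the remaining ``N - n`` unsampled trees.
    """

    y1: float
    y2: float

    def __post_init__(self) -> None:
        _check_unit("y1", self.y1)
        _check_unit("y2", self.y2)


@dataclass(frozen=True)
class SlippageDecomposition:
    """Full decomposition of a site's sampling expectations.

    Attributes
    ----------
    P : float
        Probability that no inspected tree is found infested.
    beta : float
        Sample adjustment factor conditioning the infested count in the
        sample on the non-detection event (``nan`` in the degenerate
        ``gamma*e == 1`` case, where it only ever appears multiplied by
        ``P == 0``).
    D1, D2, D3 : float
        Expected infested counts among uninspected trees (D1), among
        inspected trees given the site is declared clean (D2), and among
        inspected trees given a detection (D3).
    E : float
        Expected slippage, ``P * (D1 + D2)``.
    F : float
        Expected infested trees given detection, ``(1 - P) * D1 + n*gamma -
        P*D2`` arranged so that ``E + F == gamma * N``.
    """

    P: float
    beta: float
    D1: float
    D2: float
    D3: float
    E: float
    F: float


# ---------------------------------------------------------------------------
# vectorised primitives (used by the optimizer to precompute coefficient
# tables over sites x menu options x scenarios)
# ---------------------------------------------------------------------------


def nondetection_prob_array(gamma, e, n):
    """``(1 - gamma*e)**n`` computed as exp(n*log1p(-gamma*e)), broadcasting.

    The degenerate base ``gamma*e == 1`` gives 0 for ``n >= 1`` and 1 for
    ``n == 0``.
    """
    gamma = np.asarray(gamma, dtype=float)
    e = np.asarray(e, dtype=float)
    n = np.asarray(n, dtype=float)
    ge = gamma * e
    with np.errstate(divide="ignore", invalid="ignore"):
        log_base = np.log1p(-ge)
        out = np.exp(n * log_base)
    out = np.where((ge >= 1.0) & (n > 0), 0.0, out)
    out = np.where(n == 0, 1.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def pbeta_array(gamma, e, n):
    """``P * beta = (1 - e) * (1 - gamma*e)**(n-1)`` with the ``gamma*e == 1``
    limit taken as 0 for ``n >= 1`` (the product only ever appears multiplied
    by ``n``, so the ``n == 0`` value is irrelevant; we return ``(1-e)/(1-ge)``
    times ``P=1`` there, i.e. plain ``beta``, which the callers multiply by
    ``n == 0`` anyway)."""
    gamma = np.asarray(gamma, dtype=float)
    e = np.asarray(e, dtype=float)
    n = np.asarray(n, dtype=float)
    ge = gamma * e
    with np.errstate(divide="ignore", invalid="ignore"):
        pow_nm1 = np.exp((n - 1.0) * np.log1p(-ge))
        out = (1.0 - e) * pow_nm1
    out = np.where(ge >= 1.0, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# scalar operations on validated inputs
# ---------------------------------------------------------------------------


def prob_nondetection(inputs: SiteSamplingInputs) -> float:
    """Probability that the survey fails to detect any infested tree.

    Equals ``(1 - gamma*e)**n``; an empty sample (n = 0) can never detect,
    so the probability is 1.
    """
    return float(nondetection_prob_array(inputs.gamma, inputs.e, inputs.n))


def slippage_adjustment(gamma: float, e: float) -> float:
    """Adjustment factor ``(1 - e) / (1 - gamma*e)`` for the infested count
    in the inspected sample, conditional on non-detection.

    Raises
    ------
    ZeroDivisionError
        If ``gamma * e == 1`` (certain infestation with perfect detection),
        where the conditioning event has probability zero.
    """
    _check_unit("gamma", gamma)
    _check_unit("e", e)
    ge = gamma * e
    if ge >= 1.0:
        raise ZeroDivisionError(
            "slippage adjustment undefined for gamma*e = 1: non-detection "
            "has probability zero, so the conditional factor has a zero "
            "denominator"
        )
    return (1.0 - e) / (1.0 - ge)


def expected_slippage(inputs: SiteSamplingInputs) -> float:
    """Expected infested trees left behind when the site is declared clean.

    ``E = P*gamma*(N - n) + n*gamma*P*beta``. With no survey (n = 0) this is
    the unconditional expectation ``gamma * N``.
    """
    g, e, n, N = inputs.gamma, inputs.e, inputs.n, inputs.N
    P = nondetection_prob_array(g, e, n)
    pbeta = pbeta_array(g, e, n)
    return float(P * g * (N - n) + n * g * pbeta)


def expected_detected_infested(inputs: SiteSamplingInputs) -> float:
    """Expected infested trees at the site when the survey detects.

    ``F = gamma*(N - n)*(1 - P) + n*gamma*(1 - P*beta)``; zero when n = 0
    because detection is then impossible.
    """
    g, e, n, N = inputs.gamma, inputs.e, inputs.n, inputs.N
    if n == 0:
        return 0.0
    P = nondetection_prob_array(g, e, n)
    pbeta = pbeta_array(g, e, n)
    return float(g * (N - n) * (1.0 - P) + n * g * (1.0 - pbeta))


def residual_after_removal(
    inputs: SiteSamplingInputs, removal: RemovalFractions
) -> float:
    """Expected infested trees remaining after detection-triggered removal.

    ``gamma*(N-n)*(1-P)*(1-y2) + n*gamma*(1-P*beta)*(1-y1)``: linear in the
    removal fractions, reducing to ``expected_detected_infested`` at
    ``y1 = y2 = 0`` and to zero at complete removal.
    """
    g, e, n, N = inputs.gamma, inputs.e, inputs.n, inputs.N
    if n == 0:
        return 0.0
    P = nondetection_prob_array(g, e, n)
    pbeta = pbeta_array(g, e, n)
    return float(
        g * (N - n) * (1.0 - P) * (1.0 - removal.y2)
        + n * g * (1.0 - pbeta) * (1.0 - removal.y1)
    )


def decompose(inputs: SiteSamplingInputs) -> SlippageDecomposition:
    """Return the full slippage decomposition for one site."""
    g, e, n, N = inputs.gamma, inputs.e, inputs.n, inputs.N
    P = float(nondetection_prob_array(g, e, n))
    ge = g * e
    beta = (1.0 - e) / (1.0 - ge) if ge < 1.0 else float("nan")
    D1 = g * (N - n)
    D2 = n * g * beta if ge < 1.0 else 0.0
    E = expected_slippage(inputs)
    F = expected_detected_infested(inputs)
    # D3 solves F = (1-P) * (D1 + D3); undefined when detection is impossible
    D3 = F / (1.0 - P) - D1 if P < 1.0 else 0.0
    return SlippageDecomposition(P=P, beta=beta, D1=D1, D2=D2, D3=D3, E=E, F=F)
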