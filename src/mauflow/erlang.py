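"""Erlang loss (M/M/n/n) model and its inverse.

For a unit with ``n`` beds and offered load ``rho`` (the mean occupancy
the unit would have with unlimited beds), the Erlang B formula

    B(n, rho) = (rho**n / n!) / sum_{i=0}^{n} rho**i / i!

gives the fraction of potential admissions blocked because every bed is
occupied, and the realised mean occupancy is ``rho * (1 - B)``.  The
forward direction uses the standard stable recurrence

    B_0 = 1,   B_k = rho * B_{k-1} / (k + rho * B_{k-1})

which avoids the factorial overflow of the direct form at large ``n``
(units here reach 72 beds and beyond).  The inverse direction — recover
the load compatible with an observed occupancy — exploits that realised
occupancy is strictly increasing in ``rho``, so a bracketed bisection
finds the unique root.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ErlangResult", "erlang_loss", "occupancy_from_load", "inverse_load"]


@dataclass(frozen=True)
class ErlangResult:
    """A consistent (capacity, load, loss, occupancy) quadruple."""

    n: int
    load: float
    loss: float
    occupancy: float


def _check_n(n) -> int:
    if isinstance(n, bool) or int(n) != n:
        raise ValueError(f"bed capacity must be an integer, got {n!r}")
    n = int(n)
    if n < 0:
        raise ValueError("bed capacity must be non-negative")
    return n


def erlang_loss(n: int, load: float) -> float:
    """Blocking probability B(n, load) via the stable recurrence."""
    n = _check_n(n)
    if load < 0:
        raise ValueError("load must be non-negative")
    b = 1.0
    for k in range(1, n + 1):
        b = load * b / (k + load * b)
    return b


def occupancy_from_load(n: int, load: float) -> float:
    """Realised mean occupancy ``load * (1 - B(n, load))``."""
    n = _check_n(n)
    if n < 1:
        raise ValueError("occupancy requires at least one bed")
    return load * (1.0 - erlang_loss(n, load))


def inverse_load(n: int, observed_occupancy: float, tolerance: float = 1e-8) -> float:
    """Load whose realised occupancy matches an observed occupancy.

    Bisection on the strictly increasing map load -> occupancy; the
    initial bracket ``[occ, occ + 1]`` (occupancy never exceeds load) is
    grown geometrically until it straddles the target, then halved until
    the occupancy residual is within ``tolerance`` beds.
    """
    n = _check_n(n)
    if n < 1:
        raise ValueError("inverse_load requires at least one bed")
    if observed_occupancy < 0:
        raise ValueError("observed occupancy must be non-negative")
    if observed_occupancy >= n:
        raise ValueError(
            f"observed occupancy {observed_occupancy} is not attainable with "
            f"{n} beds: a loss system's mean occupancy is strictly below its capacity"
        )
    if observed_occupancy == 0.0:
        return 0.0
    lo = observed_occupancy
    width = 1.0
    hi = lo + width
    while occupancy_from_load(n, hi) < observed_occupancy:
        lo = hi
        width *= 2.0
        hi = lo + width
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        occ = occupancy_from_load(n, mid)
        if abs(occ - observed_occupancy) <= tolerance:
            return mid
        if occ < observed_occupancy:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("bisection failed to converge")


def erlang_result_from_load(n: int, load: float) -> ErlangResult:
    loss = erlang_loss(n, load)
    return ErlangResult(n=int(n), load=load, loss=loss, occupancy=load * (1.0 - loss))


def erlang_result_from_occupancy(n: int, occupancy: float, tolerance: float = 1e-8) -> ErlangResult:
    load = inverse_load(n, occupancy, tolerance)
    return erlang_result_from_load(n, load)
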