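"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from arborsim.fixtures import make_fixture
from arborsim.model.container import ModelContainer


@pytest.fixture()
def passive_container() -> ModelContainer:
    mtext, _ = make_fixture("passive_soma")
    return ModelContainer.from_text(mtext)


@pytest.fixture()
def hh_container() -> ModelContainer:
    mtext, _ = make_fixture("hh_soma")
    return ModelContainer.from_text(mtext)


@pytest.fixture(scope="session")
def fill_in_count():
    """Brute-force symbolic Gaussian elimination, counting fill-in edges.

    ``parents`` maps each node to its parent (None for the root); ``order`` is
    the elimination order.  Eliminating a node pairwise-connects its not-yet-
    eliminated neighbors; every edge so created is fill-in.
    """

    def _count(parents, order) -> int:
        n = len(parents)
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, p in enumerate(parents):
            if p is not None and p >= 0:
                adj[i].add(p)
                adj[p].add(i)
        eliminated: set[int] = set()
        fill = 0
        for v in order:
            nbrs = [u for u in adj[v] if u not in eliminated]
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    u, w = nbrs[a], nbrs[b]
                    if w not in adj[u]:
                        adj[u].add(w)
                        adj[w].add(u)
                        fill += 1
            eliminated.add(v)
        return fill

    return _count


@pytest.fixture(scope="session")
def hh_ode_oracle():
    """High-accuracy adaptive integration of the point-neuron HH equations.

    Integrates the identical equations (continuous rate laws, no tables) with
    scipy's LSODA at rtol 1e-10 and returns the first spike's refined
    (peak time, peak voltage).  Completely independent of the cable solver's
    tabulated/staggered scheme.
    """
    from scipy.integrate import solve_ivp
    from scipy.optimize import minimize_scalar

    def _oracle(comp, i_amp: float, t_on: float, t_end: float):
        channels = {ch.name: ch for ch in comp.channels}
        na, kd = channels["na"], channels["k"]
        gates = {g.name: g for ch in comp.channels for g in ch.gates}

        def deriv(t, y):
            v, m, h, n = y
            i_inj = i_amp if t >= t_on else 0.0
            dv = (
                -comp.g_leak * (v - comp.e_leak)
                - na.gmax * m**3 * h * (v - na.erev)
                - kd.gmax * n**4 * (v - kd.erev)
                + i_inj
            ) / comp.cm
            dm = float(gates["m"].alpha(v)) * (1 - m) - float(gates["m"].beta(v)) * m
            dh = float(gates["h"].alpha(v)) * (1 - h) - float(gates["h"].beta(v)) * h
            dn = float(gates["n"].alpha(v)) * (1 - n) - float(gates["n"].beta(v)) * n
            return [dv, dm, dh, dn]

        def steady(g, v):
            a, b = float(g.alpha(v)), float(g.beta(v))
            return a / (a + b)

        v0 = comp.v_init
        y0 = [v0, steady(gates["m"], v0), steady(gates["h"], v0), steady(gates["n"], v0)]
        # split at the stimulus discontinuity so the integrator never smooths it
        pre = solve_ivp(deriv, (0.0, t_on), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        post = solve_ivp(deriv, (t_on, t_end), pre.y[:, -1], method="LSODA",
                         rtol=1e-10, atol=1e-12, dense_output=True)
        tt = np.linspace(t_on, t_end, 20001)
        vv = post.sol(tt)[0]
        i_pk = int(np.argmax(vv))
        res = minimize_scalar(
            lambda t: -post.sol(t)[0],
            bounds=(tt[max(i_pk - 1, 0)], tt[min(i_pk + 1, len(tt) - 1)]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x), float(-res.fun)

    return _oracle


@pytest.fixture(scope="session")
def spike_peak():
    """Refine the discrete maximum of a sampled trace by parabolic interpolation."""

    def _peak(times: np.ndarray, v: np.ndarray) -> tuple[float, float]:
        i = int(np.argmax(v))
        if 0 < i < len(v) - 1:
            y1, y2, y3 = v[i - 1], v[i], v[i + 1]
            denom = y1 - 2 * y2 + y3
            off = 0.5 * (y1 - y3) / denom if denom != 0 else 0.0
            dt = times[1] - times[0]
            return float(times[i] + off * dt), float(y2 - 0.25 * (y1 - y3) * off)
        return float(times[i]), float(v[i])

    return _peak
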