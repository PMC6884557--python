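"""Analysis of translocation event collections.

The reaction coordinate s is the number of monomers that have exited the
pore to the trans side.  From per-event first-exit times and the
configuration snapshots captured at each first passage, this module builds
the per-s observable curves:

* mean exit time <t(s)> and waiting time w(s) = <t(s+1)> - <t(s)>;
* X_COM, the x component of the chain's centre of mass;
* the aspect ratio alpha = dx / (2 r) of the trans-side monomer cloud,
  with dx its axial extent past the trans plane and
  r = sqrt(y_max^2 + z_max^2) its lateral extent off the pore axis;
* the shape factor delta = R_g / R_h comparing gyration radius and
  hydrodynamic (Kirkwood) radius; small for compact globules, large for
  rods.  For scale: a uniformly filled ball has R_g = sqrt(3/5) R, so
  measured against its geometric (Stokes) radius the compact-sphere anchor
  is sqrt(3/5) ~= 0.77.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcefield import PolymerState
from .geometry import MembraneGeometry
from .protocol import STATUS_COMPLETED, TranslocationEvent


@dataclass
class ObservableSeries:
    """Per-s observable curves averaged over completed events."""

    s_axis: np.ndarray
    mean_exit_time: np.ndarray
    waiting_time: np.ndarray        # length N-1, w(s) for s = 1..N-1
    x_com: np.ndarray | None
    alpha: np.ndarray | None
    delta: np.ndarray | None
    n_events_used: int
    condition: dict

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (s, statistic)."""
        rows = []
        stats = {"mean_exit_time": self.mean_exit_time,
                 "x_com": self.x_com, "alpha": self.alpha,
                 "delta": self.delta}
        for name, values in stats.items():
            if values is None:
                continue
            for s, v in zip(self.s_axis, values):
                rows.append({**self.condition, "s": int(s),
                             "statistic": name, "value": v,
                             "n": self.n_events_used})
        for s, v in zip(self.s_axis[:-1], self.waiting_time):
            rows.append({**self.condition, "s": int(s),
                         "statistic": "waiting_time", "value": v,
                         "n": self.n_events_used})
        return pd.DataFrame(rows)


def completed(events: list[TranslocationEvent]) -> list[TranslocationEvent]:
    return [e for e in events if e.status == STATUS_COMPLETED]


def mean_exit_times(events: list[TranslocationEvent]) -> np.ndarray:
    """<t_exit(s)> for s = 1..N over completed events."""
    evs = completed(events)
    if not evs:
        raise ValueError("no completed events")
    return np.mean([e.exit_times for e in evs], axis=0)


def waiting_times(events: list[TranslocationEvent]) -> np.ndarray:
    """w(s) = <t(s+1)> - <t(s)> for s = 1..N-1."""
    return np.diff(mean_exit_times(events))


def crossing_index(curve_a: np.ndarray, curve_b: np.ndarray) -> int | None:
    """Smallest s (1-based) where sign(a - b) differs from its sign at s=1.

    Exact ties count as a crossing at that s; returns None if the curves
    never cross.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("curves must be equal-length 1-D series")
    diff = a - b
    s0 = np.sign(diff[0])
    if s0 == 0:
        return 1
    for i, d in enumerate(diff):
        if np.sign(d) != s0:
            return i + 1
    return None


def com_x(state_or_positions) -> float:
    """x component of the (mass-uniform) centre of mass."""
    pos = (state_or_positions.positions
           if isinstance(state_or_positions, PolymerState)
           else np.asarray(state_or_positions, dtype=float))
    return float(pos[:, 0].mean())


def aspect_ratio_alpha(state_or_positions, geom: MembraneGeometry) -> float:
    """alpha = dx / (2 sqrt(y_max^2 + z_max^2)) over trans-side beads.

    Undefined (NaN) when no bead is past the trans plane or when all
    trans-side beads sit exactly on the pore axis.
    """
    pos = (state_or_positions.positions
           if isinstance(state_or_positions, PolymerState)
           else np.asarray(state_or_positions, dtype=float))
    trans = pos[pos[:, 0] > geom.trans_plane_x]
    if len(trans) == 0:
        return float("nan")
    dx = float(trans[:, 0].max() - geom.trans_plane_x)
    y_max = float(np.abs(trans[:, 1] - geom.pore_center[1]).max())
    z_max = float(np.abs(trans[:, 2] - geom.pore_center[2]).max())
    r = float(np.hypot(y_max, z_max))
    if r == 0.0:
        return float("nan")
    return dx / (2.0 * r)


def gyration_radius(positions: np.ndarray) -> float:
    centred = positions - positions.mean(axis=0)
    return float(np.sqrt((centred ** 2).sum(axis=1).mean()))


def kirkwood_hydrodynamic_radius(positions: np.ndarray) -> float:
    """Kirkwood estimate: R_h^-1 = (1/N^2) sum_{i != j} 1/r_ij."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 beads")
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    if np.any(r[iu] == 0.0):
        raise ValueError("coincident beads: r_ij = 0")
    inv_sum = 2.0 * (1.0 / r[iu]).sum()
    return float(n * n / inv_sum)


def shape_factor_delta(state_or_positions) -> float:
    """delta = R_g / R_h over ALL beads (cis and trans sides)."""
    pos = (state_or_positions.positions
           if isinstance(state_or_positions, PolymerState)
           else np.asarray(state_or_positions, dtype=float))
    return gyration_radius(pos) / kirkwood_hydrodynamic_radius(pos)


def uniform_ball_anchor() -> float:
    """Compact-sphere anchor of the delta scale: R_g of a uniformly filled
    ball over its geometric (Stokes) radius.

    R_g^2 = (integral r^2 dV)/V = 3 R^2/5, so the ratio is sqrt(3/5),
    which prints as 0.77.
    """
    return float(np.sqrt(3.0 / 5.0))


ROD_ANCHOR = 4.0  # upper end of the delta scale (long-rod limit)


def com_vs_s(events: list[TranslocationEvent]) -> np.ndarray:
    """Per-s X_COM averaged over events (snapshots at each first passage)."""
    return _snapshot_series(events, lambda snap, geom: com_x(snap))


def _snapshot_series(events, fn, geom: MembraneGeometry | None = None
                     ) -> np.ndarray:
    evs = [e for e in completed(events) if e.snapshots is not None]
    if not evs:
        raise ValueError("no completed events carrying snapshots")
    n = evs[0].snapshots.shape[0]
    out = np.full(n, np.nan)
    for s in range(n):
        vals = [fn(e.snapshots[s], geom) for e in evs]
        vals = [v for v in vals if np.isfinite(v)]
        out[s] = np.mean(vals) if vals else np.nan
    return out


def build_observable_series(events: list[TranslocationEvent],
                            geom: MembraneGeometry | None = None
                            ) -> ObservableSeries:
    """Assemble every per-s curve for one condition's event collection."""
    evs = completed(events)
    if not evs:
        raise ValueError("no completed events")
    mean_t = mean_exit_times(evs)
    n = len(mean_t)
    have_snaps = all(e.snapshots is not None for e in evs)
    xc = al = de = None
    if have_snaps:
        xc = _snapshot_series(evs, lambda snap, g: com_x(snap))
        de = _snapshot_series(evs, lambda snap, g: shape_factor_delta(snap))
        if geom is not None:
            al = _snapshot_series(
                evs, lambda snap, g: aspect_ratio_alpha(snap, g), geom)
    return ObservableSeries(
        s_axis=np.arange(1, n + 1), mean_exit_time=mean_t,
        waiting_time=np.diff(mean_t), x_com=xc, alpha=al, delta=de,
        n_events_used=len(evs), condition=dict(evs[0].condition))


def translocation_time_summary(events: list[TranslocationEvent],
                               bins: int = 30) -> dict:
    """Mean, standard deviation and histogram of the translocation time."""
    evs = completed(events)
    if not evs:
        raise ValueError("no completed events")
    taus = np.array([e.total_time for e in evs])
    counts, edges = np.histogram(taus, bins=bins)
    # population sd: invariant under duplicating the event list
    return {"n": len(taus), "mean": float(taus.mean()),
            "sd": float(taus.std()) if len(taus) > 1 else 0.0,
            "histogram": {"counts": counts.tolist(),
                          "bin_edges": edges.tolist()},
            "condition": dict(evs[0].condition)}


def summary_table(events: list[TranslocationEvent]) -> pd.DataFrame:
    """Per-condition translocation-time table (one row per condition)."""
    rows = []
    df = pd.DataFrame(
        [{**e.condition, "tau": e.total_time} for e in completed(events)])
    for cond, grp in df.groupby(["pore_radius", "pore_epsilon",
                                 "pull_force"]):
        rows.append({"pore_radius": cond[0], "pore_epsilon": cond[1],
                     "pull_force": cond[2], "n": len(grp),
                     "mean_tau": grp["tau"].mean(),
                     "sd_tau": grp["tau"].std(ddof=1) if len(grp) > 1
                     else 0.0})
    return pd.DataFrame(rows)


def group_by_condition(events: list[TranslocationEvent]
                       ) -> dict[tuple, list[TranslocationEvent]]:
    out: dict[tuple, list[TranslocationEvent]] = {}
    for e in events:
        key = (e.condition["pore_radius"], e.condition["pore_epsilon"],
               e.condition["pull_force"])
        out.setdefault(key, []).append(e)
    return out
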