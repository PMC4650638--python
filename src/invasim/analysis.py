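"""Observables: success rates, single-linkage clustering of agent positions,
and group-size statistics against the realized mean energy.

Migrating groups are identified the way the field identifies density-based
clusters of tracked cells: single-linkage hierarchical clustering on
pairwise Euclidean distances, with the dendrogram cut at a fixed radius
(default 30 world units in the 800 x 800 arena) — two agents belong to one
group iff they are connected by a chain of pairwise links each strictly
below the cutoff.  The group-size summary reports the mean size of
multi-agent groups and the number of singletons separately, as two curves
against the mean depot energy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = ["success_rate", "cluster_agents", "cluster_summary",
           "run_cluster_summary"]

DEFAULT_CUTOFF = 30.0


def success_rate(result, mode: str) -> float | None:
    """Fraction of the mode's population that reached the target in time.

    Returns ``None`` (absent, not 0) if the run had no agents of that mode.
    """
    pop = result.population(mode)
    if pop == 0:
        return None
    return result.successes(mode) / pop


def cluster_agents(positions, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Partition positions into migrating groups (labels 0..k-1).

    Single-linkage dendrogram cut at the cutoff radius: links strictly below
    ``cutoff`` merge.  Requires at least one position.
    """
    positions = np.asarray(positions, dtype=np.float64)
    if positions.ndim != 2 or positions.shape[0] < 1:
        raise ValueError("need at least one position")
    n = positions.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.intp)
    z = linkage(pdist(positions), method="single")
    labels = fcluster(z, t=np.nextafter(cutoff, 0.0), criterion="distance")
    return np.asarray(labels, dtype=np.intp) - 1


def cluster_summary(trajectories: pd.DataFrame, sample_times,
                    cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Per-snapshot group statistics over the active (not yet arrived) agents.

    Returns a tidy frame with columns ``snapshot_t, n_active, n_groups,
    mean_group_size, n_singles, mean_energy``; the mean group size is over
    groups of >= 2 agents (NaN when there are none).  Snapshots with zero
    active agents are skipped.
    """
    rows = []
    times = np.asarray(trajectories["t"].unique())
    for t_want in sample_times:
        t_near = times[np.argmin(np.abs(times - t_want))]
        snap = trajectories[(trajectories["t"] == t_near)
                            & (trajectories["status"] == "active")]
        if len(snap) == 0:
            continue
        labels = cluster_agents(snap[["x", "y"]].to_numpy(), cutoff)
        sizes = np.bincount(labels)
        multi = sizes[sizes >= 2]
        rows.append({
            "snapshot_t": float(t_near),
            "n_active": int(len(snap)),
            "n_groups": int(len(multi)),
            "mean_group_size": float(multi.mean()) if len(multi) else np.nan,
            "n_singles": int(np.sum(sizes == 1)),
            "mean_energy": float(snap["e"].mean()),
        })
    return pd.DataFrame(rows)


def run_cluster_summary(result, cutoff: float = DEFAULT_CUTOFF,
                        window: tuple[float, float] = (0.25, 0.75),
                        n_snapshots: int = 20) -> pd.DataFrame:
    """Cluster statistics of one run over the mid-run sampling window
    (by default 20 snapshots over t in [0.25, 0.75] * t_max)."""
    if result.trajectories is None:
        raise ValueError("run was executed without trajectory recording")
    t_max = result.config.t_max
    times = np.linspace(window[0] * t_max, window[1] * t_max, n_snapshots)
    return cluster_summary(result.trajectories, times, cutoff)
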