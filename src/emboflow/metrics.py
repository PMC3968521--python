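"""Outcome statistics for particle runs.

Exit-branch distributions (per outlet, per perfusion territory, or per side),
normalized histograms of travel-average speed and residence time, and the
path-tortuosity statistic: the percent excess of a particle's true path
length over the centerline route length between its entry and exit vessels.
Trapped and deposited particles are reported separately and excluded from
the exit-percentage base, matching the convention of ignoring particles
caught in slow or recirculating flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hemodynamics import MM
from .particle_dynamics import ParticleStatus, TrajectoryRecord
from .vasculature import NetworkError, Territory, VascularNetwork, route_length

__all__ = [
    "ExitDistribution",
    "Histogram",
    "average_speed",
    "exit_distribution",
    "speed_histogram",
    "time_histogram",
    "tortuosity",
    "tortuosity_report",
    "case_report",
    "TERRITORY_GROUPS",
]

#: Table-style territory grouping: both MCAs together, the ACA tree, and the
#: posterior group (basilar branches + PCAs).
TERRITORY_GROUPS: dict[str, tuple[Territory, ...]] = {
    "ACAs": (Territory.ACA,),
    "MCAs": (Territory.MCA_L, Territory.MCA_R),
    "BA_PCA": (Territory.POSTERIOR,),
}


def average_speed(record: TrajectoryRecord) -> float:
    """Travel-average speed of an exited particle: path length / residence."""
    if not record.exited:
        raise ValueError("average speed is defined only for exited particles")
    if record.residence_s <= 0:
        raise ValueError("exited record has non-positive residence time")
    return record.path_length_m / record.residence_s


@dataclass
class ExitDistribution:
    """Percentages over exited particles; trapped/deposited counted aside."""

    grouping: str
    percentages: dict[str, float]
    n_exited: int
    n_trapped: int
    n_deposited: int
    empty: bool = False


def _group_of(record: TrajectoryRecord, grouping: str, net: VascularNetwork | None) -> str:
    if grouping == "outlet":
        return record.outlet  # type: ignore[return-value]
    if net is None:
        raise NetworkError(f"grouping {grouping!r} requires the network")
    seg = net.segment(record.outlet)
    if grouping == "territory":
        for name, members in TERRITORY_GROUPS.items():
            if seg.territory in members:
                return name
        return seg.territory.value
    if grouping == "side":
        x = net.node(seg.distal_node).position[0]
        return "left" if x < 0 else ("right" if x > 0 else "midline")
    raise ValueError(f"unknown grouping {grouping!r}; expected outlet/territory/side")


def exit_distribution(
    records: Sequence[TrajectoryRecord],
    grouping: str = "outlet",
    net: VascularNetwork | None = None,
) -> ExitDistribution:
    """Percent of exited particles per group (outlet, territory, or side)."""
    exited = [r for r in records if r.exited]
    n_trapped = sum(r.outcome is ParticleStatus.TRAPPED for r in records)
    n_deposited = sum(r.outcome is ParticleStatus.DEPOSITED for r in records)
    if not exited:
        return ExitDistribution(grouping, {}, 0, n_trapped, n_deposited, empty=True)
    counts: dict[str, int] = {}
    for r in exited:
        key = _group_of(r, grouping, net)
        counts[key] = counts.get(key, 0) + 1
    total = len(exited)
    pct = {k: 100.0 * v / total for k, v in sorted(counts.items())}
    return ExitDistribution(grouping, pct, total, n_trapped, n_deposited)


@dataclass
class Histogram:
    """Normalized frequencies on half-open bins (upper-inclusive last bin)."""

    edges: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)


def _histogram(values: np.ndarray, bin_width: float) -> Histogram:
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if values.size == 0:
        raise ValueError("histogram requires at least one exited particle")
    top = float(values.max())
    n_bins = max(1, int(np.ceil(top / bin_width + 1e-12)))
    edges = np.arange(0.0, (n_bins + 1) * bin_width - bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(values, bins=edges)
    return Histogram(edges, counts / counts.sum())


def speed_histogram(records: Sequence[TrajectoryRecord], bin_width: float = 0.025) -> Histogram:
    """Histogram of travel-average speeds of exited particles (m/s bins)."""
    speeds = np.array([average_speed(r) for r in records if r.exited])
    return _histogram(speeds, bin_width)


def time_histogram(records: Sequence[TrajectoryRecord], bin_width: float = 0.1) -> Histogram:
    """Histogram of residence times of exited particles (s bins)."""
    times = np.array([r.residence_s for r in records if r.exited])
    return _histogram(times, bin_width)


def tortuosity(record: TrajectoryRecord, route_length_mm: float) -> float:
    """Percent excess of the particle path over the centerline route length.

    Zero for a particle that rides the centerline; slightly negative values
    are possible when a particle cuts corners relative to the polyline route
    and are reported as computed.
    """
    if not record.exited:
        raise ValueError("tortuosity is defined only for exited particles")
    if route_length_mm <= 0:
        raise ValueError("route length must be positive")
    path_mm = record.path_length_m / MM
    return 100.0 * (path_mm - route_length_mm) / route_length_mm


def tortuosity_report(
    records: Sequence[TrajectoryRecord], net: VascularNetwork
) -> pd.DataFrame:
    """Mean tortuosity per (inlet, outlet, case) route among exited particles."""
    rows: dict[tuple[str, str, str], list[float]] = {}
    route_cache: dict[tuple[str, str], float] = {}
    for r in records:
        if not r.exited:
            continue
        key = (r.inlet_id, r.outlet)
        if key not in route_cache:
            route_cache[key] = route_length(net, r.inlet_id, r.outlet)
        rows.setdefault((r.inlet_id, r.outlet, r.case), []).append(
            tortuosity(r, route_cache[key])
        )
    return pd.DataFrame(
        [
            {
                "inlet": inlet,
                "outlet": outlet,
                "case": case,
                "n": len(vals),
                "tortuosity_pct": float(np.mean(vals)),
            }
            for (inlet, outlet, case), vals in sorted(rows.items())
        ]
    )


def case_report(
    records_by_cell: Mapping[tuple[str, str], Sequence[TrajectoryRecord]],
    net: VascularNetwork,
) -> dict[str, pd.DataFrame]:
    """Assemble per-case outcome tables from a {(case, mode): records} map.

    Returns three DataFrames: "summary" (mean travel speed and residence time
    per case and release mode), "exit_by_territory" (exit percentages in the
    table-style territory grouping, with trapped/deposited counts), and
    "tortuosity" (per named inlet-outlet route).
    """
    summary_rows = []
    exit_rows = []
    tort_frames = []
    for (case, mode), records in sorted(records_by_cell.items()):
        exited = [r for r in records if r.exited]
        speeds = [average_speed(r) for r in exited]
        times = [r.residence_s for r in exited]
        summary_rows.append(
            {
                "case": case,
                "release_mode": mode,
                "n_released": len(records),
                "n_exited": len(exited),
                "mean_speed_m_s": float(np.mean(speeds)) if speeds else np.nan,
                "mean_residence_s": float(np.mean(times)) if times else np.nan,
            }
        )
        dist = exit_distribution(records, "territory", net)
        row = {"case": case, "release_mode": mode}
        for group in TERRITORY_GROUPS:
            row[group] = dist.percentages.get(group, 0.0)
        row["n_exited"] = dist.n_exited
        row["n_trapped"] = dist.n_trapped
        row["n_deposited"] = dist.n_deposited
        exit_rows.append(row)
        tort = tortuosity_report(records, net)
        if len(tort):
            tort.insert(0, "release_mode", mode)
            tort_frames.append(tort)
    return {
        "summary": pd.DataFrame(summary_rows),
        "exit_by_territory": pd.DataFrame(exit_rows),
        "tortuosity": (
            pd.concat(tort_frames, ignore_index=True)
            if tort_frames
            else pd.DataFrame(
                columns=["release_mode", "inlet", "outlet", "case", "n", "tortuosity_pct"]
            )
        ),
    }
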