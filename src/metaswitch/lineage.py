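"""Lineage-level estimators: activation events, dwell times, elongation
rates, per-state growth, genealogy trees and dual-reporter correlation.

Event detection is plain threshold crossing on a per-frame trace (the rule
used on mother-machine movies): an event opens at the first frame at or
above threshold after a sub-threshold frame and closes at the first frame
below threshold.  Events touching either movie boundary are censored; they
are excluded from dwell statistics (a dwell needs both boundaries) but
counted in event rates (an onset does not).

Elongation is quantified as percent length increase per hour under
exponential growth, ``100*(exp(60*s) - 1)`` for the least-squares slope
``s`` of log-length versus time in 1/min, so one doubling per hour reads
100 %/hr.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .params import PCT_PER_HR_NOTE

__all__ = [
    "EVENT_COLUMNS",
    "detect_events",
    "detect_events_per_cell",
    "events_per_100hr",
    "dwell_summary",
    "elongation_rate",
    "ElongationEstimate",
    "cell_cycle_windows",
    "per_state_growth",
    "GenealogyTree",
    "build_genealogy",
    "parse_newick",
    "reporter_correlation",
    "mother_traces",
    "mother_observation_hours",
    "occupancy_from_events",
    "AllCensoredError",
]

EVENT_COLUMNS = ["trace_id", "first_frame", "last_frame", "n_frames",
                 "t_on", "t_off", "dwell_min", "censored"]

#: length ratio between consecutive frames below which a division is called
DIVISION_DROP = 0.7


class AllCensoredError(ValueError):
    """Dwell statistics requested but every event is censored."""


# ---------------------------------------------------------------------------
# event detection

def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "trace_id": pd.Series(dtype=object),
        "first_frame": pd.Series(dtype=np.int64),
        "last_frame": pd.Series(dtype=np.int64),
        "n_frames": pd.Series(dtype=np.int64),
        "t_on": pd.Series(dtype=float),
        "t_off": pd.Series(dtype=float),
        "dwell_min": pd.Series(dtype=float),
        "censored": pd.Series(dtype=bool),
    })


def detect_events(trace: Sequence[float], threshold: float,
                  frame_interval: float, *, hysteresis: float = 1.0,
                  frames: Optional[Sequence[int]] = None, t0: float = 0.0,
                  trace_id: object = None,
                  median_filter: bool = False) -> pd.DataFrame:
    """Threshold-crossing activation events on one per-frame trace.

    An event spans the frames from the first value ``>= threshold``
    (following a sub-threshold frame, else start-censored) to the last
    frame before the value drops below ``hysteresis * threshold``
    (``hysteresis <= 1``; default 1, i.e. symmetric).  ``dwell_min`` is
    exactly ``n_frames * frame_interval``.  ``median_filter`` applies an
    optional 3-frame median before detection.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        raise ValueError("trace must have at least 2 frames")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not 0 < hysteresis <= 1:
        raise ValueError("hysteresis must lie in (0, 1]")
    if median_filter:
        from scipy.ndimage import median_filter as mf
        x = mf(x, size=3, mode="nearest")
    if frames is None:
        frames = np.arange(x.size, dtype=np.int64)
    else:
        frames = np.asarray(frames, dtype=np.int64)
        if frames.size != x.size:
            raise ValueError("frames and trace must have equal length")

    close_at = hysteresis * threshold
    rows = []
    active = False
    start = 0
    for i, v in enumerate(x):
        if not active and v >= threshold:
            active = True
            start = i
        elif active and v < close_at:
            rows.append((start, i - 1, i, start == 0))
            active = False
    if active:
        rows.append((start, x.size - 1, None, True))

    out = []
    for start, last, below, censored in rows:
        n = last - start + 1
        t_on = t0 + frames[start] * frame_interval
        t_off = t0 + frames[below] * frame_interval if below is not None else np.nan
        out.append((trace_id, int(frames[start]), int(frames[last]), n,
                    t_on, t_off, n * frame_interval, bool(censored)))
    if not out:
        return _empty_events()
    return pd.DataFrame(out, columns=EVENT_COLUMNS)


def detect_events_per_cell(lineage: pd.DataFrame, column: str,
                           threshold: float, frame_interval: float,
                           **kwargs) -> pd.DataFrame:
    """Run :func:`detect_events` on every cell's own frame sequence."""
    tables = []
    for cid, sub in lineage.sort_values("frame").groupby("cell_id", sort=False):
        if len(sub) < 2:
            continue
        tables.append(detect_events(
            sub[column].to_numpy(), threshold, frame_interval,
            frames=sub["frame"].to_numpy(), trace_id=cid, **kwargs))
    if not tables:
        return _empty_events()
    return pd.concat(tables, ignore_index=True)


def default_trace_threshold(values: Sequence[float], k: float = 2.0) -> float:
    """Per-movie default activation threshold: mean + k*SD of all frame
    values (consistent with the snapshot positive-cell rule)."""
    x = np.asarray(values, dtype=float)
    return float(x.mean() + k * x.std(ddof=1))


# ---------------------------------------------------------------------------
# event-rate and dwell statistics

def _concat_events(tables) -> pd.DataFrame:
    if isinstance(tables, pd.DataFrame):
        return tables
    tables = [t for t in tables if len(t)]
    if not tables:
        return _empty_events()
    return pd.concat(tables, ignore_index=True)


def events_per_100hr(tables, total_observed_hr: float) -> float:
    """Activation onsets (censored included) per 100 hours of observation."""
    if total_observed_hr <= 0:
        raise ValueError("total_observed_hr must be > 0")
    ev = _concat_events(tables)
    return 100.0 * len(ev) / total_observed_hr


def dwell_summary(tables, frame_interval: Optional[float] = None) -> dict:
    """Mean and sample SD of dwell times over uncensored events.

    Censored events are excluded (their count is reported).  When
    ``frame_interval`` is given, ``mean_corrected_min`` adds the
    ``+frame_interval/2`` interval-censoring correction to the mean.
    """
    ev = _concat_events(tables)
    unc = ev[~ev["censored"].astype(bool)] if len(ev) else ev
    n_cens = int(len(ev) - len(unc))
    if len(unc) == 0:
        raise AllCensoredError(
            f"no uncensored events ({n_cens} censored events excluded)")
    dwell = unc["dwell_min"].to_numpy(dtype=float)
    out = {
        "mean_min": float(dwell.mean()),
        "sd_min": float(dwell.std(ddof=1)) if dwell.size > 1 else float("nan"),
        "n": int(dwell.size),
        "n_censored": n_cens,
        "single_event": dwell.size == 1,
    }
    if frame_interval is not None:
        out["mean_corrected_min"] = out["mean_min"] + frame_interval / 2.0
        out["correction"] = "+frame_interval/2 (interval censoring at frame resolution)"
    return out


def occupancy_from_events(tables, total_frames: int) -> float:
    """Fraction of observed frames lying inside detected events."""
    if total_frames <= 0:
        raise ValueError("total_frames must be > 0")
    ev = _concat_events(tables)
    return float(ev["n_frames"].sum() / total_frames)


# ---------------------------------------------------------------------------
# elongation

@dataclass
class ElongationEstimate:
    rate_pct_per_hr: float
    window: Tuple[float, float]
    n_frames_used: int
    r2: float
    slope_per_min: float
    definition: str = field(default=PCT_PER_HR_NOTE)


def elongation_rate(lengths: Sequence[float], frame_interval: float,
                    t: Optional[Sequence[float]] = None) -> ElongationEstimate:
    """Least-squares exponential elongation rate over one cell-cycle window.

    Fits ``ln(length)`` against time; requires >= 3 frames, positive
    lengths, and no division (length drop) inside the window.  The result
    is invariant to rescaling the length unit.
    """
    L = np.asarray(lengths, dtype=float)
    if L.size < 3:
        raise ValueError("elongation window needs at least 3 frames")
    if np.any(L <= 0):
        raise ValueError("lengths must be > 0")
    if np.any(L[1:] / L[:-1] < DIVISION_DROP):
        raise ValueError("length drop inside window: division must not occur "
                         "within an elongation window")
    tt = (np.arange(L.size) * frame_interval if t is None
          else np.asarray(t, dtype=float))
    y = np.log(L)
    slope, intercept = np.polyfit(tt, y, 1)
    pred = slope * tt + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rate = 100.0 * (math.exp(60.0 * slope) - 1.0)
    return ElongationEstimate(rate_pct_per_hr=rate,
                              window=(float(tt[0]), float(tt[-1])),
                              n_frames_used=int(L.size), r2=r2,
                              slope_per_min=float(slope))


def cell_cycle_windows(lineage: pd.DataFrame, min_frames: int = 3
                       ) -> List[dict]:
    """Split each cell's trace at division-scale length drops and return
    per-cycle windows (>= ``min_frames`` frames, no division inside)."""
    windows = []
    for cid, sub in lineage.sort_values("frame").groupby("cell_id", sort=False):
        L = sub["length_um"].to_numpy(dtype=float)
        fr = sub["frame"].to_numpy()
        tt = sub["t_min"].to_numpy(dtype=float)
        # boundaries where length drops by a division-scale factor
        cuts = np.flatnonzero(L[1:] / L[:-1] < DIVISION_DROP) + 1
        for seg in np.split(np.arange(L.size), cuts):
            if seg.size >= min_frames:
                windows.append(dict(cell_id=cid, frames=fr[seg], t=tt[seg],
                                    lengths=L[seg]))
    return windows


def per_state_growth(lineage: pd.DataFrame, events: pd.DataFrame,
                     frame_interval: float, min_class_n: int = 50) -> dict:
    """Mean +/- SEM elongation rate of in-event ("on") versus out-of-event
    ("off") cell-cycle windows.

    Elongation windows are cell-cycle segments of constant event coverage
    (cycles are split where an event of the same trace starts or ends, so a
    window measures growth within one state episode); each window with at
    least 3 frames is assigned "on" when at least 50% of its frames lie
    inside an event (ties assigned "on").  Classes with no windows are
    reported absent; ``sufficient_n`` flags whether both present classes
    reach ``min_class_n`` windows.
    """
    cover: Dict[object, set] = {}
    for _, ev in events.iterrows():
        s = cover.setdefault(ev["trace_id"], set())
        s.update(range(int(ev["first_frame"]), int(ev["last_frame"]) + 1))

    rates = {"on": [], "off": []}
    for w in cell_cycle_windows(lineage):
        frames = w["frames"]
        on_frames = cover.get(w["cell_id"], set())
        inside = np.array([f in on_frames for f in frames])
        cuts = np.flatnonzero(inside[1:] != inside[:-1]) + 1
        for seg in np.split(np.arange(len(frames)), cuts):
            if seg.size < 3:
                continue
            frac_on = inside[seg].mean()
            cls = "on" if frac_on >= 0.5 else "off"
            est = elongation_rate(w["lengths"][seg], frame_interval,
                                  t=w["t"][seg])
            rates[cls].append(est.rate_pct_per_hr)

    out = {"definition": PCT_PER_HR_NOTE, "window_rule":
           ">=50% of frames inside an event -> on (ties on)"}
    for cls in ("on", "off"):
        arr = np.asarray(rates[cls], dtype=float)
        if arr.size == 0:
            out[cls] = None
            continue
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan")
        out[cls] = {"mean_pct_per_hr": float(arr.mean()), "sem": sem,
                    "n": int(arr.size)}
    present = [out[c] for c in ("on", "off") if out[c] is not None]
    out["sufficient_n"] = bool(present) and all(c["n"] >= min_class_n for c in present)
    return out


# ---------------------------------------------------------------------------
# genealogy

@dataclass
class GenealogyTree:
    """Cell-division genealogy: nodes are cells (one cell cycle each in
    pad-mode tables), edges run mother -> daughter, every division has
    exactly two daughters."""

    graph: nx.DiGraph
    roots: List[int]
    frame_interval: float

    def leaves(self) -> List[int]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def depth(self, node: int) -> int:
        d = 0
        while True:
            preds = list(self.graph.predecessors(node))
            if not preds:
                return d
            node = preds[0]
            d += 1

    def node_table(self) -> pd.DataFrame:
        rows = [{"cell_id": n, **self.graph.nodes[n]} for n in self.graph.nodes]
        return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)

    def to_newick(self, annotate: bool = False) -> str:
        """One Newick line per founder; branch lengths are cell-cycle
        durations in minutes.  ``annotate`` adds NHX comments with the
        per-cycle mean alsS fluorescence."""
        def fmt(node: int) -> str:
            attrs = self.graph.nodes[node]
            children = sorted(self.graph.successors(node))
            label = f"c{node}:{attrs['duration_min']:g}"
            if annotate:
                label += f"[&&NHX:expr={attrs['mean_f_alsS']:.6g}]"
            if children:
                return "(" + ",".join(fmt(c) for c in children) + ")" + label
            return label
        return "\n".join(f"({fmt(r)});" for r in sorted(self.roots))


def build_genealogy(lineage: pd.DataFrame,
                    frame_interval: Optional[float] = None) -> GenealogyTree:
    """Genealogy tree from a pad-mode lineage table.

    Node attributes: ``birth_t``, ``end_t``, ``duration_min``
    (n_frames * frame_interval), per-cycle mean fluorescence of both
    reporters, and ``fate``.  Raises on orphan parent references and on
    divisions with a number of daughters other than two.
    """
    if frame_interval is None:
        frame_interval = lineage.attrs.get("frame_interval")
    if frame_interval is None:
        t = np.sort(lineage["t_min"].unique())
        frame_interval = float(np.diff(t).min()) if t.size > 1 else 1.0

    g = nx.DiGraph()
    ids = set(int(i) for i in lineage["cell_id"].unique())
    per_cell = lineage.sort_values("frame").groupby("cell_id", sort=False)
    parent_of = {}
    for cid, sub in per_cell:
        cid = int(cid)
        pid = int(sub["parent_id"].iloc[0])
        parent_of[cid] = pid
        g.add_node(
            cid,
            birth_t=float(sub["t_min"].iloc[0]),
            end_t=float(sub["t_min"].iloc[-1]),
            duration_min=float(len(sub) * frame_interval),
            mean_f_sucC=float(sub["f_sucC"].mean()),
            mean_f_alsS=float(sub["f_alsS"].mean()),
            fate=str(sub["fate"].iloc[-1]),
        )
    orphans = sorted(cid for cid, pid in parent_of.items()
                     if pid != -1 and pid not in ids)
    if orphans:
        raise ValueError(f"orphan parent references for cells: {orphans}")
    for cid, pid in parent_of.items():
        if pid != -1:
            g.add_edge(pid, cid)

    bad = sorted(n for n in g.nodes if g.out_degree(n) not in (0, 2))
    if bad:
        raise ValueError(
            f"division must produce exactly 2 daughters; offending cells: {bad}")

    for pid, cid in g.edges:
        if g.nodes[cid]["birth_t"] <= g.nodes[pid]["birth_t"]:
            raise ValueError(f"birth times must increase along lineages "
                             f"(cells {pid} -> {cid})")

    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    return GenealogyTree(graph=g, roots=sorted(roots),
                         frame_interval=float(frame_interval))


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;]+")


def parse_newick(text: str) -> List[dict]:
    """Parse the Newick dialect written by :meth:`GenealogyTree.to_newick`
    back into nested ``{name, length, children, expr}`` dicts (one per
    founder line)."""
    trees = []
    for line in text.strip().splitlines():
        line = line.strip()
        if not line:
            continue
        pos = 0

        def parse_node():
            nonlocal pos
            node = {"children": [], "name": None, "length": None, "expr": None}
            if line[pos] == "(":
                pos += 1
                while True:
                    node["children"].append(parse_node())
                    if line[pos] == ",":
                        pos += 1
                        continue
                    if line[pos] == ")":
                        pos += 1
                        break
            m = re.match(r"[^(),;:\[]*", line[pos:])
            label = m.group(0)
            pos += len(label)
            node["name"] = label or None
            if pos < len(line) and line[pos] == ":":
                m = re.match(r":([0-9.eE+-]+)", line[pos:])
                node["length"] = float(m.group(1))
                pos += len(m.group(0))
            if pos < len(line) and line[pos] == "[":
                end = line.index("]", pos)
                comment = line[pos + 1:end]
                pos = end + 1
                m = re.search(r"expr=([0-9.eE+-]+)", comment)
                if m:
                    node["expr"] = float(m.group(1))
            return node

        root = parse_node()
        if pos < len(line) and line[pos] == ";":
            pos += 1
        # unwrap the outer "(...)" wrapper if it is a bare container
        if root["name"] is None and root["length"] is None \
                and len(root["children"]) == 1:
            root = root["children"][0]
        trees.append(root)
    return trees


# ---------------------------------------------------------------------------
# dual-reporter correlation

def reporter_correlation(x: Sequence[float], y: Sequence[float]) -> dict:
    """Pearson and Spearman correlation of paired per-cell reporter means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in a channel")
    xc, yc = x - x.mean(), y - y.mean()
    return {
        "pearson": float(stats.pearsonr(xc, yc).statistic),
        "spearman": float(stats.spearmanr(xc, yc).statistic),
        "n": int(x.size),
    }


# ---------------------------------------------------------------------------
# mother-machine helpers

def mother_traces(lineage: pd.DataFrame) -> Dict[int, pd.DataFrame]:
    """Per-channel trace of the persisting mother cell (the channel founder,
    ``parent_id == -1``), sorted by frame."""
    mothers = lineage[lineage["parent_id"] == -1]
    return {int(ch): sub.sort_values("frame").reset_index(drop=True)
            for ch, sub in mothers.groupby("channel_id", sort=True)}


def mother_observation_hours(lineage: pd.DataFrame,
                             frame_interval: Optional[float] = None) -> float:
    """Total observed mother-cell time in hours (frames x frame interval)."""
    if frame_interval is None:
        frame_interval = lineage.attrs.get("frame_interval", 12.0)
    n = sum(len(tr) for tr in mother_traces(lineage).values())
    return n * frame_interval / 60.0
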