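"""Agent-based simulator of interacting metabolic subpopulations.

The generative model follows the interaction scheme inferred for clonal
*B. subtilis* cultures: a competence-linked sucC+ state is entered and left
at constant (quorum- and glucose-gated) Poisson rates and secretes acetate;
accumulated acetate induces, through a Hill response, a second alsS+ state
whose cells take acetate up and convert it to acetoin (a pH-neutral overflow
product).  Both active states carry a multiplicative growth penalty, and all
cells are slowed by a saturating acetate toxicity factor
``K_tox/(K_tox + acetate)``.

Three culture geometries share one engine:

``batch``
    closed, carbon-limited shaking culture; emits an environment trajectory
    and per-frame fluorescence snapshots of every cell.
``mother_machine``
    dead-end microfluidic channels under constant media; the cell at the
    capped end persists indefinitely, daughters are pushed down the channel
    and washed out past the channel capacity.  Environment is fixed.
``pad``
    agarose-pad microcolony: full genealogy is retained (each division
    closes the mother cell and opens two new daughter cells) and the colony
    shares a closed acetate/acetoin pool while the carbon sources are
    treated as an unlimited reservoir.

Cell elongation is exponential with per-cell-cycle lognormal rate noise.
Reporters are stable (production minus growth dilution, no degradation) and
partition concentration-conservingly at division.  All stochasticity flows
from one ``numpy`` generator seeded from the scenario config.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .params import CellState, ScenarioConfig, SwitchParams
from .snapshots import SnapshotSample

__all__ = [
    "simulate_batch",
    "simulate_mother_machine",
    "simulate_pad",
    "reporter_update",
    "BatchResult",
    "PadResult",
    "LINEAGE_COLUMNS",
]

log = logging.getLogger("metaswitch")

LINEAGE_COLUMNS = [
    "cell_id", "parent_id", "channel_id", "frame", "t_min", "length_um",
    "f_sucC", "f_alsS", "state_sucC", "state_alsS", "fate",
]

OD0 = 0.05  # OD600 proxy assigned to the founding biomass of a batch culture


# ---------------------------------------------------------------------------
# single-cell reporter kinetics

def reporter_update(state: CellState, dt: float, params: SwitchParams,
                    growth_rate: Optional[float] = None) -> CellState:
    """Advance one cell's reporters by ``dt`` minutes.

    Fluorescence concentration follows production (``beta_on`` in the on
    state, else ``beta_off``) minus dilution by growth; there is no active
    degradation.  The update integrates the linear ODE exactly over ``dt``
    assuming the state and growth rate are constant within the step, so at
    steady state ``F* = beta/r`` and relaxation toward it has e-folding time
    ``1/r``.

    ``growth_rate`` (1/min) defaults to the cell's state-dependent rate
    ``r_base * penalty_sucC^sucC * penalty_alsS^alsS`` with no environmental
    modulation.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if growth_rate is None:
        growth_rate = params.r_base
        if state.sucC_state:
            growth_rate *= params.penalty_sucC
        if state.alsS_state:
            growth_rate *= params.penalty_alsS
    r = growth_rate
    new_f = []
    for on, f in ((state.sucC_state, state.F_sucC), (state.alsS_state, state.F_alsS)):
        beta = params.beta_on if on else params.beta_off
        if r > 0:
            fstar = beta / r
            new_f.append(fstar + (f - fstar) * math.exp(-r * dt))
        else:
            new_f.append(f + beta * dt)
    return replace(
        state,
        length=state.length * math.exp(r * dt),
        F_sucC=new_f[0],
        F_alsS=new_f[1],
    )


# ---------------------------------------------------------------------------
# vectorised cell population

class _Cells:
    """Struct-of-arrays container for the live population."""

    def __init__(self) -> None:
        self.cell_id = np.empty(0, dtype=np.int64)
        self.parent_id = np.empty(0, dtype=np.int64)
        self.channel = np.empty(0, dtype=np.int64)
        self.position = np.empty(0, dtype=np.int64)
        self.birth_t = np.empty(0, dtype=float)
        self.length = np.empty(0, dtype=float)
        self.f_suc = np.empty(0, dtype=float)
        self.f_als = np.empty(0, dtype=float)
        self.s_suc = np.empty(0, dtype=bool)
        self.s_als = np.empty(0, dtype=bool)
        self.gnoise = np.empty(0, dtype=float)
        self.next_id = 0

    _FIELDS = ("cell_id", "parent_id", "channel", "position", "birth_t",
               "length", "f_suc", "f_als", "s_suc", "s_als", "gnoise")

    def __len__(self) -> int:
        return self.cell_id.size

    def append(self, **cols) -> None:
        for name in self._FIELDS:
            arr = getattr(self, name)
            new = np.asarray(cols[name], dtype=arr.dtype)
            setattr(self, name, np.concatenate([arr, new]))

    def keep(self, mask: np.ndarray) -> None:
        for name in self._FIELDS:
            setattr(self, name, getattr(self, name)[mask])


def _draw_gnoise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Lognormal per-cycle growth factors with mean 1."""
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _found(cells: _Cells, rng: np.random.Generator, n: int,
           params: SwitchParams, r_init: float,
           channels: Optional[np.ndarray] = None) -> None:
    """Create founder cells, all in the off/off state at reporter steady state."""
    u = rng.random(n)
    # uniform cell-cycle phase; a 2 µm birth length when division is disabled
    birth = 0.5 * params.L_div if math.isfinite(params.L_div) else 2.0
    length = birth * np.exp(u * math.log(2.0))
    f0 = params.beta_off / r_init if r_init > 0 else 0.0
    cells.append(
        cell_id=np.arange(n, dtype=np.int64),
        parent_id=np.full(n, -1, dtype=np.int64),
        channel=channels if channels is not None else np.full(n, -1, dtype=np.int64),
        position=np.zeros(n, dtype=np.int64),
        birth_t=np.zeros(n),
        length=length,
        f_suc=np.full(n, f0),
        f_als=np.full(n, f0),
        s_suc=np.zeros(n, dtype=bool),
        s_als=np.zeros(n, dtype=bool),
        gnoise=_draw_gnoise(rng, n, params.growth_cv),
    )
    cells.next_id = n


# ---------------------------------------------------------------------------
# engine

@dataclass
class _Env:
    glucose: float
    malate: float
    acetate: float
    acetoin: float
    produced: float = 0.0   # cumulative acetate secreted
    consumed: float = 0.0   # cumulative acetate taken up


@dataclass
class BatchResult:
    """Closed-culture run: environment time course plus per-frame snapshots."""
    env: pd.DataFrame
    snapshots: List[SnapshotSample]
    acetate_produced: float
    acetate_consumed: float


@dataclass
class PadResult:
    """Microcolony run: full-genealogy lineage table plus shared environment."""
    lineage: pd.DataFrame
    env: pd.DataFrame
    acetate_produced: float
    acetate_consumed: float


def _growth_rates(cells: _Cells, params: SwitchParams, acetate: float,
                  carbon_factor: float) -> np.ndarray:
    r = params.r_base * cells.gnoise * (params.toxicity(acetate) * carbon_factor)
    if len(cells):
        r = r * np.where(cells.s_suc, params.penalty_sucC, 1.0)
        r = r * np.where(cells.s_als, params.penalty_alsS, 1.0)
    return r


def _update_reporters(cells: _Cells, r: np.ndarray, dt: float,
                      params: SwitchParams) -> None:
    for f_name, s_name in (("f_suc", "s_suc"), ("f_als", "s_als")):
        f = getattr(cells, f_name)
        beta = np.where(getattr(cells, s_name), params.beta_on, params.beta_off)
        pos = r > 0
        fstar = np.divide(beta, r, out=np.zeros_like(f), where=pos)
        newf = np.where(pos, fstar + (f - fstar) * np.exp(-r * dt), f + beta * dt)
        setattr(cells, f_name, newf)


def _switch_states(cells: _Cells, rng: np.random.Generator, dt: float,
                   k_on_suc: float, k_off_suc: float,
                   k_on_als: float, k_off_als: float) -> None:
    n = len(cells)
    u = rng.random((n, 2))
    for j, (s_name, k_on, k_off) in enumerate(
            (("s_suc", k_on_suc, k_off_suc), ("s_als", k_on_als, k_off_als))):
        s = getattr(cells, s_name)
        p_on = -np.expm1(-k_on * dt)
        p_off = -np.expm1(-k_off * dt)
        flip = np.where(s, u[:, j] < p_off, u[:, j] < p_on)
        setattr(cells, s_name, np.where(flip, ~s, s))


def _measure(rng: np.random.Generator, f: np.ndarray, cv: float) -> np.ndarray:
    """Recorded fluorescence: multiplicative lognormal measurement noise."""
    if cv <= 0:
        rng.normal(size=f.size)  # keep the stream layout independent of cv
        return f.copy()
    sigma = math.sqrt(math.log(1.0 + cv**2))
    z = rng.normal(size=f.size)
    return f * np.exp(sigma * z - 0.5 * sigma**2)


def _site_fractions(rng: np.random.Generator, n: int, div_cv: float) -> np.ndarray:
    # div_cv is the CV of the division-site position around mid-cell
    z = rng.normal(size=n)
    return np.clip(0.5 + 0.5 * div_cv * z, 0.1, 0.9)


def _divide_keep_mother(cells: _Cells, rng: np.random.Generator, t: float,
                        params: SwitchParams, fates: dict,
                        capacity: Optional[int]) -> None:
    """Division for batch and mother-machine modes: the dividing cell keeps
    its identity (proximal daughter), the distal daughter gets a new id.

    In mother-machine mode the new cell is inserted distally (position+1),
    everything further down the channel shifts, and cells shifted past the
    channel capacity are washed out.
    """
    if not math.isfinite(params.L_div):
        return
    div = np.flatnonzero(cells.length >= params.L_div)
    if div.size == 0:
        return
    frac = _site_fractions(rng, div.size, params.div_cv)
    old_len = cells.length[div]
    cells.length[div] = frac * old_len
    cells.gnoise[div] = _draw_gnoise(rng, div.size, params.growth_cv)

    new_ids = cells.next_id + np.arange(div.size, dtype=np.int64)
    cells.next_id += div.size
    new_positions = cells.position[div] + 1

    if capacity is not None:
        # shift cells distal to each division site, most-distal first
        order = np.lexsort((-cells.position[div], cells.channel[div]))
        for k in order:
            i = div[k]
            mask = (cells.channel == cells.channel[i]) & \
                   (cells.position > cells.position[i])
            cells.position[mask] += 1
        new_positions = cells.position[div] + 1

    cells.append(
        cell_id=new_ids,
        parent_id=cells.cell_id[div],
        channel=cells.channel[div],
        position=new_positions,
        birth_t=np.full(div.size, t),
        length=(1.0 - frac) * old_len,
        f_suc=cells.f_suc[div],
        f_als=cells.f_als[div],
        s_suc=cells.s_suc[div],
        s_als=cells.s_als[div],
        gnoise=_draw_gnoise(rng, div.size, params.growth_cv),
    )

    if capacity is not None:
        washed = cells.position >= capacity
        if washed.any():
            for cid in cells.cell_id[washed]:
                fates[int(cid)] = "washed_out"
            cells.keep(~washed)


def _divide_pad(cells: _Cells, rng: np.random.Generator, t: float,
                params: SwitchParams, fates: dict) -> None:
    """Pad-mode division: the mother cell ends, two new daughters appear."""
    if not math.isfinite(params.L_div):
        return
    div = np.flatnonzero(cells.length >= params.L_div)
    if div.size == 0:
        return
    frac = _site_fractions(rng, div.size, params.div_cv)
    old_len = cells.length[div]
    mothers = cells.cell_id[div]
    for cid in mothers:
        fates[int(cid)] = "divided"

    ids_a = cells.next_id + np.arange(div.size, dtype=np.int64)
    ids_b = ids_a + div.size
    cells.next_id += 2 * div.size

    daughters = dict(
        cell_id=np.concatenate([ids_a, ids_b]),
        parent_id=np.concatenate([mothers, mothers]),
        channel=np.concatenate([cells.channel[div]] * 2),
        position=np.concatenate([cells.position[div]] * 2),
        birth_t=np.full(2 * div.size, t),
        length=np.concatenate([frac * old_len, (1.0 - frac) * old_len]),
        f_suc=np.concatenate([cells.f_suc[div]] * 2),
        f_als=np.concatenate([cells.f_als[div]] * 2),
        s_suc=np.concatenate([cells.s_suc[div]] * 2),
        s_als=np.concatenate([cells.s_als[div]] * 2),
        gnoise=_draw_gnoise(rng, 2 * div.size, params.growth_cv),
    )
    keep = np.ones(len(cells), dtype=bool)
    keep[div] = False
    cells.keep(keep)
    cells.append(**daughters)


def _emit_lineage(rec: list, cells: _Cells, rng: np.random.Generator,
                  frame: int, t: float, params: SwitchParams) -> None:
    rec.append(dict(
        cell_id=cells.cell_id.copy(),
        parent_id=cells.parent_id.copy(),
        channel_id=cells.channel.copy(),
        frame=np.full(len(cells), frame, dtype=np.int64),
        t_min=np.full(len(cells), t),
        length_um=cells.length.copy(),
        f_sucC=_measure(rng, cells.f_suc, params.meas_cv),
        f_alsS=_measure(rng, cells.f_als, params.meas_cv),
        state_sucC=cells.s_suc.astype(np.int64),
        state_alsS=cells.s_als.astype(np.int64),
    ))


def _lineage_frame(rec: list, fates: dict) -> pd.DataFrame:
    if not rec:
        return pd.DataFrame(columns=LINEAGE_COLUMNS)
    cols = {k: np.concatenate([r[k] for r in rec]) for k in rec[0]}
    df = pd.DataFrame(cols)
    df = df.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)
    fate = np.array(["live"] * len(df), dtype=object)
    last = df.groupby("cell_id", sort=False)["frame"].idxmax()
    for cid, idx in last.items():
        fate[idx] = fates.get(int(cid), "live")
    df["fate"] = fate
    return df[LINEAGE_COLUMNS]


def _run(params: SwitchParams, config: ScenarioConfig):
    """Shared engine; returns mode-specific results."""
    params = config.apply_knockouts(params)
    rng = np.random.default_rng(config.seed)
    mode = config.mode
    dt = config.dt
    cells = _Cells()
    fates: dict = {}

    env = _Env(config.glucose, config.malate, config.acetate, config.acetoin)
    if mode == "mother_machine":
        env = _Env(0.0, 0.0, config.media_acetate, 0.0)
        quorum = config.media_quorum if config.media_quorum is not None else params.quorum
        carbon_factor, entry_gate, sec_gate = 1.0, 1.0, 1.0
        n_ch = config.n_channels
        _found(cells, rng, n_ch, params,
               params.r_base * params.toxicity(env.acetate),
               channels=np.arange(n_ch, dtype=np.int64))
    else:
        quorum = params.quorum if config.media_quorum is None else config.media_quorum
        r_init = params.r_base * params.toxicity(env.acetate)
        _found(cells, rng, config.n_founders, params, r_init)

    env_rows: list = []
    snap: List[SnapshotSample] = []
    lineage_rec: list = []
    biomass0 = max(cells.length.sum(), 1e-300)

    def record_frame(frame: int, t: float) -> None:
        biomass = cells.length.sum()
        env_rows.append((t, biomass, env.glucose, env.malate, env.acetate, env.acetoin))
        if mode == "batch":
            od = OD0 * biomass / biomass0 if len(cells) else 0.0
            for rep, f in (("sucC", cells.f_suc), ("alsS", cells.f_als)):
                if len(cells) == 0:
                    continue
                snap.append(SnapshotSample(
                    t=t, od=od, values=_measure(rng, f, params.meas_cv),
                    reporter_name=rep))
        else:
            _emit_lineage(lineage_rec, cells, rng, frame, t, params)

    record_frame(0, 0.0)

    chemostatic = mode == "mother_machine"
    track_carbon = mode == "batch"
    capacity = config.channel_capacity if chemostatic else None

    for step in range(1, config.n_frames * config.env_substeps + 1):
        t = step * dt
        if not chemostatic:
            carbon = env.glucose + env.malate
            carbon_factor = carbon / (params.K_carbon + carbon) if carbon > 0 else 0.0
            od = OD0 * cells.length.sum() / biomass0
            entry_gate = params.competence_window(od)
            sec_gate = carbon / (params.K_sec + carbon)

        r = _growth_rates(cells, params, env.acetate, carbon_factor)
        old_len = cells.length
        new_len = old_len * np.exp(r * dt)
        growth = float((new_len - old_len).sum())
        cells.length = new_len
        _update_reporters(cells, r, dt, params)

        if track_carbon:
            demand = params.yield_carbon * growth
            avail = env.glucose + env.malate
            used = min(demand, avail)
            if demand > avail:
                log.debug("carbon pool exhausted at t=%.1f min; clamping", t)
            if avail > 0:
                env.glucose = max(env.glucose - used * env.glucose / avail, 0.0)
                env.malate = max(env.malate - used * env.malate / avail, 0.0)

        if not chemostatic:
            n_suc = int(cells.s_suc.sum())
            n_als = int(cells.s_als.sum())
            produced = params.p_A * n_suc * sec_gate * dt
            if track_carbon:
                # overflow acetate is drawn from the carbon pool
                # (glucose -> 2 acetate scale: 0.5 pool-mol per acetate-mol)
                avail = env.glucose + env.malate
                produced = min(produced, 2.0 * avail)
                drain = 0.5 * produced
                if avail > 0:
                    env.glucose = max(env.glucose - drain * env.glucose / avail, 0.0)
                    env.malate = max(env.malate - drain * env.malate / avail, 0.0)
            demand = params.c_A * n_als * dt
            consumed = min(demand, env.acetate + produced)
            env.acetate = env.acetate + produced - consumed
            env.acetoin += params.y_acetoin * consumed
            env.produced += produced
            env.consumed += consumed

        k_on_suc = params.k_on_sucC * quorum * entry_gate
        k_on_als = params.k_on_alsS(env.acetate)
        _switch_states(cells, rng, dt, k_on_suc, params.k_off_sucC,
                       k_on_als, params.k_off_alsS)

        if mode == "pad":
            _divide_pad(cells, rng, t, params, fates)
        else:
            _divide_keep_mother(cells, rng, t, params, fates, capacity)

        if step % config.env_substeps == 0:
            record_frame(step // config.env_substeps, t)

    env_df = pd.DataFrame(
        env_rows,
        columns=["t_min", "biomass", "glucose_mM", "malate_mM",
                 "acetate_mM", "acetoin_mM"],
    )
    env_df.attrs["acetate_produced"] = env.produced
    env_df.attrs["acetate_consumed"] = env.consumed

    if mode == "batch":
        return BatchResult(env_df, snap, env.produced, env.consumed)
    lineage = _lineage_frame(lineage_rec, fates)
    lineage.attrs["frame_interval"] = config.frame_interval
    lineage.attrs["mode"] = mode
    if mode == "mother_machine":
        return lineage
    return PadResult(lineage, env_df, env.produced, env.consumed)


# ---------------------------------------------------------------------------
# public entry points

def simulate_batch(params: SwitchParams, config: ScenarioConfig) -> BatchResult:
    """Closed shaking-culture run on a finite glucose/malate pool.

    Acetate is secreted by sucC+ cells (glucose-gated), taken up by alsS+
    cells, and converted to acetoin at ``y_acetoin`` mol/mol; all growth is
    slowed by the acetate toxicity factor.  Returns the environment time
    course and per-frame fluorescence snapshots for both reporters.
    """
    if config.mode != "batch":
        raise ValueError("config.mode must be 'batch'")
    return _run(params, config)


def simulate_mother_machine(params: SwitchParams, config: ScenarioConfig) -> pd.DataFrame:
    """Chemostatic mother-machine run at fixed media composition.

    Returns a lineage table (one row per cell per frame).  Per channel, the
    founder cell (``parent_id == -1``) is the mother at the capped end and
    persists for the whole movie; daughters are shifted distally at each
    division and silently washed out past ``channel_capacity``.
    """
    if config.mode != "mother_machine":
        raise ValueError("config.mode must be 'mother_machine'")
    return _run(params, config)


def simulate_pad(params: SwitchParams, config: ScenarioConfig) -> PadResult:
    """Agarose-pad microcolony with a shared closed acetate/acetoin pool.

    The full genealogy is retained: each division closes the mother row
    (fate ``divided``) and opens two daughter cells referencing it via
    ``parent_id``.  Carbon sources are held constant (pad reservoir).
    """
    if config.mode != "pad":
        raise ValueError("config.mode must be 'pad'")
    return _run(params, config)
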