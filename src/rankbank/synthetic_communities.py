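"""Synthetic OTU tables with the structure the analysis assumes.

Three generators:

* :func:`bank_community` — a "bank model" community: a handful of
  abundant OTUs holding a fixed share of the community on a geometric
  ladder, above a large tail of rare OTUs with lognormal weights.
* :func:`ktw_snapshot` — one snapshot of a kill-the-winner boom-and-crash
  cycle: a long drift in which the abundant group shrinks from
  ``steady_group`` members to a single dominant OTU, a near-instant
  crash that spreads the winner's mass across scavengers, and a
  relaxation back to the steady state.
* :func:`generate_dataset` — a month x depth sampling design with
  persistent, seasonal, depth-restricted and sporadic OTUs, multinomial
  read sampling, and matching metadata.

All generators are deterministic given their seed; per-sample streams
are spawned from a single root ``SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .median_rank import RankAbundance
from .otu_io import OtuTable, SampleMetadata

__all__ = [
    "BankModelParams",
    "KtwParams",
    "DatasetDesign",
    "bank_community",
    "ktw_snapshot",
    "ktw_snapshot_vector",
    "sample_counts",
    "generate_dataset",
    "bats_design",
    "block_dataset",
]


@dataclass(frozen=True)
class BankModelParams:
    """Knobs for the abundant-plus-bank community shape."""

    n_abundant: int = 3
    abundant_mass: float = 0.6
    geometric_ratio: float = 0.6
    s_bank: int = 500
    bank_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_abundant < 1:
            raise ValueError("n_abundant must be >= 1")
        if not 0.0 < self.abundant_mass < 1.0:
            raise ValueError("abundant_mass must be in (0, 1)")
        if not 0.0 < self.geometric_ratio <= 1.0:
            raise ValueError("geometric_ratio must be in (0, 1]")
        if self.s_bank < 0:
            raise ValueError("s_bank must be >= 0")
        if self.s_bank == 0:
            raise ValueError(
                "s_bank = 0 with abundant_mass < 1 leaves unassigned mass"
            )


def _geometric_fractions(n: int, ratio: float, mass: float) -> np.ndarray:
    w = ratio ** np.arange(n)
    return mass * w / w.sum()


def bank_community(
    params: BankModelParams,
    seed: int | None = None,
    sample_id: str | None = None,
) -> RankAbundance:
    """Draw one bank-model community.

    Abundant fractions follow a normalized geometric series carrying
    ``abundant_mass``; bank fractions are i.i.d. lognormal weights
    normalized to the remaining mass.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    abundant = _geometric_fractions(
        params.n_abundant, params.geometric_ratio, params.abundant_mass
    )
    w = rng.lognormal(mean=0.0, sigma=params.bank_sigma, size=params.s_bank)
    bank = (1.0 - params.abundant_mass) * w / w.sum()
    return RankAbundance.from_values(
        np.concatenate([abundant, bank]), sample_id=sample_id
    )


# ---------------------------------------------------------------------------
# kill-the-winner cycle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KtwParams:
    """One kill-the-winner cycle.

    The cycle is split into three phases by ``phase_durations``
    ``(d1, d2, d3)``, ordered slow drift > relaxation > crash
    (``d1 > d3 > d2``):

    1. drift: the abundant group shrinks stepwise from ``steady_group``
       members to 1 while the top OTU's share rises from ``f_start``; in
       a terminal sliver of relative width ``dominance_window`` the top
       share pushes past 0.5 up to ``f_max``;
    2. crash: the winner's mass is split equally between its remnant and
       ``n_competitors`` scavengers;
    3. relaxation: linear return to the phase-1 starting composition.
    """

    phase_durations: tuple[float, float, float] = (0.95, 0.01, 0.04)
    f_start: float = 0.30
    f_max: float = 0.62
    n_competitors: int = 7
    steady_group: int = 4
    dominance_window: float = 0.002
    bank: BankModelParams = field(default_factory=BankModelParams)
    seed: int = 0

    def __post_init__(self) -> None:
        d1, d2, d3 = self.phase_durations
        if abs(d1 + d2 + d3 - 1.0) > 1e-12:
            raise ValueError("phase durations must sum to 1")
        if not d1 > d3 > d2 > 0:
            raise ValueError("phase durations must satisfy d1 > d3 > d2 > 0")
        if not 0.0 < self.f_start < 0.5:
            raise ValueError("f_start must be in (0, 0.5)")
        if not self.f_max > 0.5:
            raise ValueError("f_max must exceed 0.5")
        if self.n_competitors < 1:
            raise ValueError("n_competitors must be >= 1")
        if self.steady_group < 2:
            raise ValueError("steady_group must be >= 2")
        if not 0.0 < self.dominance_window < 1.0:
            raise ValueError("dominance_window must be in (0, 1)")
        co = (0.5 - self.f_start) / (self.steady_group - 1)
        if co > self.f_start:
            raise ValueError(
                "co-abundant share exceeds f_start; raise f_start or steady_group"
            )


def _capped_bank(weights: np.ndarray, mass: float, cap: float) -> np.ndarray:
    """Scale weights to total ``mass`` with every entry <= ``cap``.

    Excess above the cap is redistributed proportionally; raises if the
    cap makes the mass unplaceable.
    """
    if mass <= 0:
        return np.zeros_like(weights)
    if cap * weights.size < mass - 1e-12:
        raise ValueError("bank cap too small to hold the bank mass")
    p = mass * weights / weights.sum()
    for _ in range(100):
        over = p > cap
        if not over.any():
            return p
        excess = float(np.sum(p[over] - cap))
        p[over] = cap
        under = ~over
        p[under] += excess * weights[under] / weights[under].sum()
    raise RuntimeError("bank capping failed to converge")


def _ktw_bank_weights(params: KtwParams) -> np.ndarray:
    rng = np.random.default_rng(params.bank.seed)
    return rng.lognormal(mean=0.0, sigma=params.bank.bank_sigma,
                         size=params.bank.s_bank)


def _ktw_phase1_vector(params: KtwParams, u: float, weights: np.ndarray) -> np.ndarray:
    """Full composition vector at phase-1 coordinate ``u`` in [0, 1)."""
    g0 = params.steady_group
    eps = params.dominance_window
    co = (0.5 - params.f_start) / (g0 - 1)
    if u < 1.0 - eps:
        v = u / (1.0 - eps)
        m = g0 - (g0 - 1) * v                 # target median rank, 4 -> 1
        f1 = params.f_start + (0.5 - params.f_start) * v
        g = int(math.ceil(m - 1e-12))
    else:
        w = (u - (1.0 - eps)) / eps           # position inside the sliver
        f1 = 0.5 + (params.f_max - 0.5) * min(w / 0.5, 1.0)
        g = 1
    n_co = g - 1
    vec = np.zeros(1 + (g0 - 1) + params.n_competitors + params.bank.s_bank)
    vec[0] = f1
    vec[1 : 1 + n_co] = co
    bank_mass = 1.0 - f1 - n_co * co
    cap = 0.9 * min(f1, co)
    vec[1 + (g0 - 1) + params.n_competitors :] = _capped_bank(weights, bank_mass, cap)
    return vec


def _ktw_crash_vector(params: KtwParams, weights: np.ndarray) -> np.ndarray:
    g0 = params.steady_group
    share = params.f_max / (params.n_competitors + 1)
    vec = np.zeros(1 + (g0 - 1) + params.n_competitors + params.bank.s_bank)
    vec[0] = share
    vec[1 + (g0 - 1) : 1 + (g0 - 1) + params.n_competitors] = share
    bank_mass = 1.0 - params.f_max
    vec[1 + (g0 - 1) + params.n_competitors :] = _capped_bank(
        weights, bank_mass, 0.9 * share
    )
    return vec


def ktw_snapshot_vector(params: KtwParams, t: float) -> np.ndarray:
    """Full composition vector (fixed OTU panel, zeros kept) at phase ``t``.

    Panel order: winner, ``steady_group - 1`` co-abundant OTUs,
    ``n_competitors`` scavengers, then the bank tail.
    """
    if not 0.0 <= t < 1.0:
        raise ValueError(f"cycle phase t must be in [0, 1), got {t}")
    d1, d2, _ = params.phase_durations
    weights = _ktw_bank_weights(params)
    if t < d1:
        return _ktw_phase1_vector(params, t / d1, weights)
    if t < d1 + d2:
        return _ktw_crash_vector(params, weights)
    s = (t - d1 - d2) / (1.0 - d1 - d2)
    crash = _ktw_crash_vector(params, weights)
    start = _ktw_phase1_vector(params, 0.0, weights)
    return (1.0 - s) * crash + s * start


def ktw_snapshot(params: KtwParams, t: float) -> RankAbundance:
    """Community composition at cycle phase ``t`` in ``[0, 1)``.

    Deterministic given ``(params, t)``: the bank tail is drawn once
    from the bank seed and shared by every snapshot of the cycle.
    """
    return RankAbundance.from_values(
        ktw_snapshot_vector(params, t), sample_id=f"ktw_t{t:.6f}"
    )


def sample_counts(
    fractions: RankAbundance | Sequence[float],
    depth: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multinomial read sampling of a composition at a given read depth."""
    if isinstance(fractions, RankAbundance):
        fractions = fractions.fractions
    p = np.asarray(fractions, dtype=float)
    if depth < 1:
        raise ValueError("read depth must be >= 1")
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("fractions must be non-negative and sum to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.multinomial(int(depth), p / p.sum())


# ---------------------------------------------------------------------------
# month x depth dataset design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetDesign:
    """Sampling layout plus OTU occupancy structure.

    ``depths`` maps each ``(month, year)`` cruise to its depth list.
    Occupancy classes: the abundant OTUs and ``n_persistent_bank`` bank
    OTUs are present everywhere; seasonal OTUs only in their month;
    depth-restricted OTUs only inside ``restricted_depth_range``;
    sporadic OTUs appear independently per sample with probability
    ``sporadic_p``.  Read depths are drawn log-triangular between
    ``read_depth = (min, mode, max)``.
    """

    cruises: tuple = ()
    depths: tuple = ()  # tuple of (cruise, tuple-of-depths), aligned with cruises
    n_persistent_bank: int = 200
    n_seasonal: int = 60            # per season (March and September)
    n_depth_restricted: int = 60
    restricted_depth_range: tuple[float, float] = (0.0, 160.0)
    n_sporadic: int = 180
    sporadic_p: float = 0.15
    read_depth: tuple[int, int, int] = (288, 3028, 12791)
    structure_boost: float = 5.0

    def __post_init__(self) -> None:
        if not self.cruises:
            raise ValueError("design needs at least one cruise")
        if len(self.depths) != len(self.cruises):
            raise ValueError("depths must align with cruises")
        for _, ds in self.depths:
            if any(d < 0 for d in ds):
                raise ValueError("depths must be non-negative")
        if not 0.0 <= self.sporadic_p <= 1.0:
            raise ValueError("sporadic_p must be in [0, 1]")
        lo, mode, hi = self.read_depth
        if not 1 <= lo <= mode <= hi:
            raise ValueError("read_depth must satisfy 1 <= min <= mode <= max")

    @property
    def samples(self) -> list[tuple[str, int, float]]:
        """Flat (month, year, depth) list, one entry per sample."""
        out = []
        for (month, year), (_, ds) in zip(self.cruises, self.depths):
            for d in ds:
                out.append((month, year, float(d)))
        return out

    def occupancy(self, bank: BankModelParams) -> dict[str, str]:
        """otu_id -> occupancy class for the full OTU panel."""
        classes: dict[str, str] = {}
        i = 0

        def take(n: int, label: str) -> None:
            nonlocal i
            for _ in range(n):
                i += 1
                classes[f"Otu{i:04d}"] = label

        take(bank.n_abundant, "persistent")
        take(self.n_persistent_bank, "persistent")
        take(self.n_seasonal, "seasonal-March")
        take(self.n_seasonal, "seasonal-September")
        take(self.n_depth_restricted, "depth-restricted")
        take(self.n_sporadic, "sporadic")
        return classes


def bats_design(**overrides) -> DatasetDesign:
    """The study's five-cruise month x depth layout (85 samples).

    Depths 0-400 m on every cruise (180 m only in 2008/2011, 250 m only
    in 2010/2011); 500-1,000 m only in 2008 and 2011.
    """
    cruises = (
        ("September", 2008),
        ("March", 2010),
        ("September", 2010),
        ("March", 2011),
        ("September", 2011),
    )
    base = [0, 20, 40, 60, 80, 100, 120, 140, 160, 200, 300, 400]
    deep = [500, 600, 700, 800, 900, 1000]
    depths = []
    for month, year in cruises:
        ds = list(base)
        if year in (2008, 2011):
            ds.append(180)
        if year in (2010, 2011):
            ds.append(250)
        if year in (2008, 2011):
            ds.extend(deep)
        depths.append(((month, year), tuple(sorted(ds))))
    return DatasetDesign(cruises=cruises, depths=tuple(depths), **overrides)


def _sample_id(month: str, year: int, depth: float) -> str:
    return f"{month[:3]}{year}_{int(depth):04d}m"


def generate_dataset(
    design: DatasetDesign,
    bank: BankModelParams | None = None,
    seed: int = 0,
) -> tuple[OtuTable, SampleMetadata]:
    """Generate an OTU count table and matching metadata for a design.

    Per sample: eligible OTUs are selected by occupancy class, the
    abundant geometric ladder goes to the persistent abundant OTUs, bank
    mass is spread over eligible tail OTUs by lognormal weights (boosted
    for in-class seasonal/depth-restricted OTUs), and reads are drawn
    multinomially at a log-triangular read depth.
    """
    if bank is None:
        bank = BankModelParams()
    classes = design.occupancy(bank)
    otu_ids = list(classes)
    cls = np.array([classes[o] for o in otu_ids])
    abundant_idx = np.arange(bank.n_abundant)
    tail_idx = np.arange(bank.n_abundant, len(otu_ids))
    lo, mode, hi = design.read_depth

    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(design.samples))
    abundant = _geometric_fractions(bank.n_abundant, bank.geometric_ratio,
                                    bank.abundant_mass)
    d_lo, d_hi = design.restricted_depth_range

    counts = np.zeros((len(design.samples), len(otu_ids)), dtype=np.int64)
    meta_rows = []
    sample_ids = []
    for row, ((month, year, depth), ss) in enumerate(zip(design.samples, streams)):
        rng = np.random.default_rng(ss)
        sid = _sample_id(month, year, depth)
        sample_ids.append(sid)
        meta_rows.append(
            {"sample_id": sid, "month": month, "year": year, "depth_m": depth}
        )
        tail_cls = cls[tail_idx]
        eligible = np.ones(tail_idx.size, dtype=bool)
        eligible[tail_cls == "seasonal-March"] = month == "March"
        eligible[tail_cls == "seasonal-September"] = month == "September"
        eligible[tail_cls == "depth-restricted"] = d_lo <= depth <= d_hi
        sporadic = tail_cls == "sporadic"
        eligible[sporadic] = rng.random(int(sporadic.sum())) < design.sporadic_p

        frac = np.zeros(len(otu_ids))
        frac[abundant_idx] = abundant
        w = rng.lognormal(0.0, bank.bank_sigma, size=int(eligible.sum()))
        boost = np.isin(
            tail_cls[eligible],
            ["seasonal-March", "seasonal-September", "depth-restricted"],
        )
        w = w * np.where(boost, design.structure_boost, 1.0)
        frac[tail_idx[eligible]] = (1.0 - bank.abundant_mass) * w / w.sum()

        reads = int(round(math.exp(
            rng.triangular(math.log(lo), math.log(mode), math.log(hi))
        )))
        counts[row] = rng.multinomial(reads, frac / frac.sum())

    table = OtuTable(sample_ids=sample_ids, otu_ids=otu_ids, counts=counts,
                     label="synthetic")
    meta = SampleMetadata(table=pd.DataFrame(meta_rows))
    return table, meta


def block_dataset(
    seasons: Sequence[str] = ("March", "September"),
    depth_zones: Sequence[str] = ("shallow", "deep"),
    samples_per_block: int = 8,
    n_block_otus: int = 5,
    block_mass: float = 0.8,
    s_bank: int = 100,
    bank_sigma: float = 1.0,
    read_depth: int = 2000,
    seed: int = 0,
) -> tuple[OtuTable, pd.DataFrame]:
    """Season x depth-zone block-structured dataset for clustering checks.

    Each block owns a private set of abundant OTUs carrying
    ``block_mass``; all blocks share one rare bank.  Returns the count
    table and a frame with columns sample_id, month, depth_zone, block.
    """
    blocks = [(m, z) for m in seasons for z in depth_zones]
    otu_ids = []
    for b in range(len(blocks)):
        otu_ids += [f"Block{b + 1}_Otu{j + 1}" for j in range(n_block_otus)]
    otu_ids += [f"Bank_Otu{j + 1}" for j in range(s_bank)]

    root = np.random.SeedSequence(seed)
    streams = iter(root.spawn(len(blocks) * samples_per_block))
    ladder = _geometric_fractions(n_block_otus, 0.6, block_mass)

    rows, labels = [], []
    for b, (month, zone) in enumerate(blocks):
        for i in range(samples_per_block):
            rng = np.random.default_rng(next(streams))
            frac = np.zeros(len(otu_ids))
            jitter = rng.lognormal(0.0, 0.15, size=n_block_otus)
            own = ladder * jitter
            frac[b * n_block_otus : (b + 1) * n_block_otus] = (
                block_mass * own / own.sum()
            )
            w = rng.lognormal(0.0, bank_sigma, size=s_bank)
            frac[len(blocks) * n_block_otus :] = (1.0 - block_mass) * w / w.sum()
            sid = f"{month[:3]}_{zone}_{i + 1:02d}"
            rows.append(rng.multinomial(read_depth, frac))
            labels.append(
                {"sample_id": sid, "month": month, "depth_zone": zone,
                 "block": f"{month[:3]}-{zone}"}
            )
    table = OtuTable(
        sample_ids=[r["sample_id"] for r in labels],
        otu_ids=otu_ids,
        counts=np.array(rows),
        label="blocks",
    )
    return table, pd.DataFrame(labels)
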