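"""Agent-based forward-in-time engine on a resistance surface.

Generations are discrete and non-overlapping: each step, individuals
disperse, reproduce, and then all adults die; the surviving offspring are the
next generation's breeding adults. Dispersal is undirected: with probability
0.5 an individual performs up to 10 sequential Queen's-case steps through
traversable cells (the default ``walk`` kernel); a ``ring`` kernel that jumps
straight to a uniformly chosen habitable cell at the largest feasible
Chebyshev distance is available as an alternative. Culvert cells embedded in
a barrier carry a per-generation transit quota (3 distinct animals may
occupy or move through the cell per generation).

Reproduction is within-cell: cells holding both sexes recruit
``E = N + r N (1 - N/K)`` expected offspring with mothers/fathers drawn from
the cell's females/males; a lone occupant reproduces uniparentally at the
same logistic rate (hatch-style persistence of isolated agents), while
multi-occupant single-sex cells recruit nothing (mate limitation).
Inheritance is Mendelian; each allele copy mutates with probability 0.0005
per generation (k-allele model over the founder state space by default).

Internally the population is stored as flat numpy arrays (one row per
individual) rather than per-agent objects: the model is agent-based in its
rules, array-based in its execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .founders import FounderPanel, LocusFrequencyTable
from .landscape import ResistanceSurface

#: per-cell seeding counts by density label (equal to the per-cell K of the
#: scenario surfaces, so initial sizes are 1875 / 8750 / 12500 on 625 cells)
SEED_COUNT = {"low": 3, "moderate": 14, "high": 20}


def growth_rate_from_annual(annual_rate: float = 0.01, breeding_years: int = 48) -> float:
    """Per-generation growth rate from an annual rate over the breeding span.

    The default 1%/year over 48 breeding years (average lifespan minus age at
    maturity) gives the 0.48 per-generation rate used throughout.
    """
    return annual_rate * breeding_years


@dataclass
class SimulationConfig:
    """Knobs of the forward engine, with the study's default values."""

    dispersal_probability: float = 0.5
    max_dispersal_cells: int = 10
    growth_rate: float = 0.48
    mutation_rate: float = 0.0005
    n_generations: int = 200
    sample_interval: int = 5
    n_replicates: int = 30
    mutation_model: str = "kam"  # "kam" (k-allele) or "smm" (single-step)
    dispersal_kernel: str = "walk"  # "walk" (Queen-step path) or "ring"
    mating_system: str = "fallback"  # "fallback" (lone occupants reproduce) or "strict"

    def __post_init__(self):
        for name in ("dispersal_probability", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("max_dispersal_cells", "n_generations", "sample_interval",
                     "n_replicates"):
            if getattr(self, name) < 1 and name != "n_generations":
                raise ValueError(f"{name} must be positive")
        if self.mutation_model not in {"kam", "smm"}:
            raise ValueError("mutation_model must be 'kam' or 'smm'")
        if self.dispersal_kernel not in {"walk", "ring"}:
            raise ValueError("dispersal_kernel must be 'walk' or 'ring'")
        if self.mating_system not in {"fallback", "strict"}:
            raise ValueError("mating_system must be 'fallback' or 'strict'")


@dataclass
class Individual:
    """Object view of one agent (the engine itself is array-based)."""

    id: int
    sex: str  # "male" | "female"
    cell: tuple[int, int]
    genotype: np.ndarray  # (n_loci, 2)


@dataclass
class PopulationState:
    """All living individuals at one generation.

    ``sex`` is 0 for female, 1 for male. ``genotypes`` has shape
    (n, n_loci, 2). ``last_info`` carries per-generation bookkeeping
    (mutation counts, culvert crossings) from the step that produced it.
    """

    row: np.ndarray
    col: np.ndarray
    sex: np.ndarray
    genotypes: np.ndarray
    loci: list[LocusFrequencyTable]
    generation: int = 0
    replicate: int = 0
    extinct: bool = False
    last_info: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.row)

    def individuals(self) -> list[Individual]:
        return [
            Individual(
                id=i,
                sex="male" if self.sex[i] else "female",
                cell=(int(self.row[i]), int(self.col[i])),
                genotype=self.genotypes[i],
            )
            for i in range(self.n)
        ]

    def copy(self) -> "PopulationState":
        return replace(
            self,
            row=self.row.copy(),
            col=self.col.copy(),
            sex=self.sex.copy(),
            genotypes=self.genotypes.copy(),
            last_info=dict(self.last_info),
        )


def _empty_state(loci, generation, replicate) -> PopulationState:
    z = np.empty(0, dtype=np.int16)
    return PopulationState(
        row=z.copy(), col=z.copy(), sex=z.copy(),
        genotypes=np.empty((0, len(loci), 2), dtype=np.int16),
        loci=loci, generation=generation, replicate=replicate, extinct=True,
    )


def initialize_population(
    surface: ResistanceSurface,
    density: str,
    founders: FounderPanel,
    seed=None,
) -> PopulationState:
    """Seed every habitable cell with ``min(seed_count, K)`` individuals.

    Seed counts are 3/14/20 per cell for low/moderate/high density
    (``variable`` seeds each cell at its own K). Genotypes are drawn from the
    founder panel (without replacement when it is large enough) and sexes are
    i.i.d. 1:1.
    """
    rng = np.random.default_rng(seed)
    if density == "variable":
        per_cell = surface.carrying.copy()
    elif density in SEED_COUNT:
        per_cell = np.minimum(SEED_COUNT[density], surface.carrying)
    else:
        raise ValueError(f"unknown density {density!r}")
    per_cell = np.where(surface.habitable, per_cell, 0)
    total = int(per_cell.sum())
    if total == 0:
        raise ValueError("surface has no habitable capacity to seed")

    rows_grid, cols_grid = np.indices(surface.shape)
    row = np.repeat(rows_grid.ravel(), per_cell.ravel()).astype(np.int16)
    col = np.repeat(cols_grid.ravel(), per_cell.ravel()).astype(np.int16)
    if founders.n >= total:
        pick = rng.choice(founders.n, size=total, replace=False)
    else:
        pick = rng.integers(founders.n, size=total)
    genotypes = founders.genotypes[pick].astype(np.int16)
    sex = rng.integers(2, size=total).astype(np.int8)
    return PopulationState(
        row=row, col=col, sex=sex, genotypes=genotypes, loci=founders.loci
    )


# ---------------------------------------------------------------------------
# dispersal candidate tables

class _DispersalTables:
    """Per-origin destination candidates for one quota state of a surface.

    For every traversable origin cell: the largest Chebyshev distance
    d <= max_d at which some habitable cell is reachable by an 8-connected
    path of length d, the flat indices of those candidate cells, and a small
    bitmask per candidate of which culvert cells a crossing must transit
    (0 = no quota cell involved).
    """

    def __init__(self, surface: ResistanceSurface, open_culverts: frozenset,
                 max_d: int):
        nr, nc = surface.shape
        n_cells = nr * nc
        traversable = surface.habitable.ravel().copy()
        culvert_flat = [r * nc + c for r, c in surface.culvert_cells]
        for i, flat in enumerate(culvert_flat):
            if i not in open_culverts:
                traversable[flat] = False

        dist = _grid_path_distances(traversable, nr, nc)
        if surface.culvert_cells:
            no_culvert = traversable.copy()
            for flat in culvert_flat:
                no_culvert[flat] = False
            dist_closed = _grid_path_distances(no_culvert, nr, nc)
        else:
            dist_closed = dist

        rr, cc = np.divmod(np.arange(n_cells), nc)
        self.candidates: list[np.ndarray | None] = [None] * n_cells
        self.masks: list[np.ndarray | None] = [None] * n_cells
        self.dsel = np.zeros(n_cells, dtype=np.int8)
        open_list = sorted(open_culverts)
        for o in np.nonzero(traversable)[0]:
            cheb = np.maximum(np.abs(rr - rr[o]), np.abs(cc - cc[o]))
            do = dist[o]
            for d in range(max_d, 0, -1):
                cand = np.nonzero((cheb == d) & (do == d))[0]
                if len(cand):
                    self.candidates[o] = cand
                    self.dsel[o] = d
                    mask = np.zeros(len(cand), dtype=np.uint8)
                    if culvert_flat:
                        needs = dist_closed[o, cand] > d
                        for bit, ci in enumerate(open_list):
                            cf = culvert_flat[ci]
                            on_path = dist[o, cf] + dist[cf, cand] == d
                            mask |= np.where(needs & on_path, 1 << ci, 0).astype(np.uint8)
                        # destination itself a culvert counts as entering it
                        for ci in open_list:
                            mask |= np.where(cand == culvert_flat[ci], 1 << ci, 0).astype(np.uint8)
                    self.masks[o] = mask
                    break


def _grid_path_distances(traversable: np.ndarray, nr: int, nc: int) -> np.ndarray:
    """All-pairs 8-connected path lengths through traversable cells."""
    n = nr * nc
    rows, cols, data = [], [], []
    idx = np.arange(n)
    rr, cc = np.divmod(idx, nc)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nrr, ncc = rr + dr, cc + dc
            ok = (
                (nrr >= 0) & (nrr < nr) & (ncc >= 0) & (ncc < nc)
                & traversable & traversable[np.clip(nrr, 0, nr - 1) * nc
                                            + np.clip(ncc, 0, nc - 1)]
            )
            rows.append(idx[ok])
            cols.append((nrr * nc + ncc)[ok])
            data.append(np.ones(ok.sum()))
    graph = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return shortest_path(graph, method="D", unweighted=True)


def _get_tables(surface: ResistanceSurface, open_culverts: frozenset,
                max_d: int) -> _DispersalTables:
    cache = getattr(surface, "_dispersal_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(surface, "_dispersal_cache", cache)
    key = (open_culverts, max_d)
    if key not in cache:
        cache[key] = _DispersalTables(surface, open_culverts, max_d)
    return cache[key]


def disperse(
    state: PopulationState,
    surface: ResistanceSurface,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Move each individual with probability ``dispersal_probability``.

    The default ``walk`` kernel performs ``max_dispersal_cells`` sequential
    Queen's-case steps through traversable cells, settling at the endpoint.
    The ``ring`` kernel instead jumps to a uniformly chosen habitable cell at
    the largest Chebyshev distance reachable by a path of that length.
    Either way, per-generation culvert transit quotas are enforced: at most
    K distinct animals may enter or traverse each culvert cell per
    generation; an individual whose crossing options are exhausted redraws
    among the still-open moves (staying put if none exist).
    """
    if config.dispersal_kernel == "walk":
        return _disperse_walk(state, surface, config, rng)
    return _disperse_ring(state, surface, config, rng)


def _neighbor_tables(surface: ResistanceSurface):
    """Per-cell traversable Queen neighbors, with and without culvert cells.

    Returns (table_open, count_open, table_closed, count_closed); tables are
    (n_cells, 8) arrays of flat indices padded with -1.
    """
    cached = getattr(surface, "_walk_cache", None)
    if cached is not None:
        return cached
    nr, nc = surface.shape
    n_cells = nr * nc
    trav = surface.habitable
    culverts = {r * nc + c for r, c in surface.culvert_cells}

    def build(allowed):
        table = np.full((n_cells, 8), -1, dtype=np.int64)
        count = np.zeros(n_cells, dtype=np.int64)
        for r in range(nr):
            for c in range(nc):
                flat = r * nc + c
                k = 0
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and trav[rr, cc]:
                            dest = rr * nc + cc
                            if allowed(dest):
                                table[flat, k] = dest
                                k += 1
                count[flat] = k
        return table, count

    open_t, open_c = build(lambda d: True)
    if culverts:
        closed_t, closed_c = build(lambda d: d not in culverts)
    else:
        closed_t, closed_c = open_t, open_c
    cached = (open_t, open_c, closed_t, closed_c)
    object.__setattr__(surface, "_walk_cache", cached)
    return cached


def _disperse_walk(state, surface, config, rng) -> PopulationState:
    n = state.n
    if n == 0:
        return state
    nr, nc = surface.shape
    table_o, count_o, table_c, count_c = _neighbor_tables(surface)
    culvert_flat = np.array(
        [r * nc + c for r, c in surface.culvert_cells], dtype=np.int64
    )
    quota = {int(f): int(surface.carrying.ravel()[f]) for f in culvert_flat}
    crossings = {i: 0 for i in range(len(culvert_flat))}
    if len(culvert_flat) > 8:
        raise NotImplementedError("more than 8 quota cells not supported")

    moving = rng.random(n) < config.dispersal_probability
    flat = state.row.astype(np.int64) * nc + state.col
    pos = flat[moving].copy()
    m = len(pos)
    visited = np.zeros(m, dtype=np.uint8)  # bitmask of culverts already counted

    for _ in range(config.max_dispersal_cells):
        cnt = count_o[pos]
        ok = cnt > 0
        draw = (rng.random(m) * np.maximum(cnt, 1)).astype(np.int64)
        nxt = np.where(ok, table_o[pos, draw], pos)
        if len(culvert_flat):
            entering = np.nonzero(np.isin(nxt, culvert_flat) & (nxt != pos))[0]
            if len(entering):
                rng.shuffle(entering)
                for w in entering:
                    dest = int(nxt[w])
                    ci = int(np.nonzero(culvert_flat == dest)[0][0])
                    if visited[w] >> ci & 1:
                        continue  # already counted this generation
                    if quota[dest] > 0:
                        quota[dest] -= 1
                        crossings[ci] += 1
                        visited[w] |= 1 << ci
                        continue
                    # quota exhausted: redraw among neighbors that are not
                    # exhausted culverts (already-visited culverts stay open
                    # to this walker)
                    row = table_o[pos[w]]
                    allowed = []
                    for d in row:
                        if d < 0:
                            continue
                        if d in quota and quota[d] == 0:
                            cj = int(np.nonzero(culvert_flat == d)[0][0])
                            if not (visited[w] >> cj & 1):
                                continue
                        allowed.append(d)
                    nxt[w] = allowed[int(rng.integers(len(allowed)))] if allowed else pos[w]
        pos = nxt
    flat[moving] = pos
    state.row = (flat // nc).astype(np.int16)
    state.col = (flat % nc).astype(np.int16)
    state.last_info = dict(state.last_info, culvert_crossings=crossings)
    return state


def _disperse_ring(state, surface, config, rng) -> PopulationState:
    n = state.n
    if n == 0:
        return state
    nr, nc = surface.shape
    moving = rng.random(n) < config.dispersal_probability
    flat = state.row.astype(np.int64) * nc + state.col
    new_flat = flat.copy()
    crossings = {i: 0 for i in range(len(surface.culvert_cells))}

    quota = {i: int(surface.carrying[r, c])
             for i, (r, c) in enumerate(surface.culvert_cells)}
    all_open = frozenset(i for i, q in quota.items() if q > 0)
    tables = _get_tables(surface, all_open, config.max_dispersal_cells)

    movers = np.nonzero(moving)[0]
    if len(movers) == 0:
        state.last_info = dict(state.last_info, culvert_crossings=crossings)
        return state

    # bulk draw destinations per origin cell under the all-open quota state
    mover_flat = flat[movers]
    order = np.argsort(mover_flat, kind="stable")
    sorted_movers = movers[order]
    sorted_flat = mover_flat[order]
    uniq, starts = np.unique(sorted_flat, return_index=True)
    starts = list(starts) + [len(sorted_flat)]
    drawn_mask = np.zeros(len(movers), dtype=np.uint8)  # aligned to sorted_movers
    drawn_dest = np.full(len(movers), -1, dtype=np.int64)
    for k, o in enumerate(uniq):
        cand = tables.candidates[o]
        lo, hi = starts[k], starts[k + 1]
        if cand is None:
            drawn_dest[lo:hi] = o  # nowhere reachable: stay
            continue
        pick = rng.integers(len(cand), size=hi - lo)
        drawn_dest[lo:hi] = cand[pick]
        drawn_mask[lo:hi] = tables.masks[o][pick]

    if not surface.culvert_cells:
        new_flat[sorted_movers] = drawn_dest
    else:
        # quota-free moves commit in bulk; quota-relevant moves resolve in
        # random order against the per-generation transit counters
        free = drawn_mask == 0
        new_flat[sorted_movers[free]] = drawn_dest[free]
        pending = np.nonzero(~free)[0]
        rng.shuffle(pending)
        for j in pending:
            ind = sorted_movers[j]
            dest, mask = drawn_dest[j], int(drawn_mask[j])
            while True:
                feas = [ci for ci in range(len(quota))
                        if (mask >> ci) & 1 and quota[ci] > 0]
                if feas:
                    ci = feas[int(rng.integers(len(feas)))]
                    quota[ci] -= 1
                    crossings[ci] += 1
                    new_flat[ind] = dest
                    break
                # redraw under the current quota state
                open_now = frozenset(i for i, q in quota.items() if q > 0)
                t2 = _get_tables(surface, open_now, config.max_dispersal_cells)
                cand = t2.candidates[flat[ind]]
                if cand is None:
                    new_flat[ind] = flat[ind]
                    break
                pick = int(rng.integers(len(cand)))
                dest, mask = int(cand[pick]), int(t2.masks[flat[ind]][pick])
                if mask == 0:
                    new_flat[ind] = dest
                    break

    state.row = (new_flat // nc).astype(np.int16)
    state.col = (new_flat % nc).astype(np.int16)
    state.last_info = dict(state.last_info, culvert_crossings=crossings)
    return state


def reproduce(
    state: PopulationState,
    surface: ResistanceSurface,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Produce the recruit cohort by within-cell mating.

    Cells holding at least one male and one female recruit
    ``E = N + r N (1 - N/K)`` offspring in expectation (floor plus a
    Bernoulli remainder); each recruit draws its mother and father uniformly
    with replacement from the cell's females/males, inherits one uniformly
    chosen allele per parent per locus, and is sexed 1:1. A lone occupant
    reproduces uniparentally at the same logistic rate (unless
    ``mating_system='strict'``); multi-occupant single-sex cells recruit
    nothing. Returns (row, col, sex, genotypes) arrays for the cohort.
    """
    nr, nc = surface.shape
    n = state.n
    loci_count = state.genotypes.shape[1]
    empty = (
        np.empty(0, np.int16), np.empty(0, np.int16), np.empty(0, np.int8),
        np.empty((0, loci_count, 2), np.int16),
    )
    if n == 0:
        return empty
    flat = state.row.astype(np.int64) * nc + state.col
    k_flat = surface.carrying.ravel()
    if np.any(k_flat[flat] == 0):
        raise RuntimeError("individual occupies a K=0 cell (dispersal bug)")

    n_cells = nr * nc
    males = state.sex == 1
    nm = np.bincount(flat[males], minlength=n_cells)
    nf = np.bincount(flat[~males], minlength=n_cells)
    ntot = nm + nf
    eligible = (nm >= 1) & (nf >= 1)
    if config.mating_system == "fallback":
        eligible |= ntot == 1
    cells = np.nonzero(eligible)[0]
    if len(cells) == 0:
        return empty

    N = ntot[cells].astype(float)
    K = k_flat[cells].astype(float)
    expected = np.maximum(N + config.growth_rate * N * (1.0 - N / K), 0.0)
    base = np.floor(expected).astype(np.int64)
    extra = rng.random(len(cells)) < (expected - base)
    recruits = base + extra
    total = int(recruits.sum())
    if total == 0:
        return empty

    # indices of mothers/fathers: individuals sorted by cell, with per-cell
    # offsets, so a uniform within-cell draw is a single gather
    order = np.argsort(flat, kind="stable")
    starts = np.concatenate([[0], np.cumsum(ntot)])[:-1]
    f_idx = np.nonzero(~males)[0]
    m_idx = np.nonzero(males)[0]
    f_sorted = f_idx[np.argsort(flat[f_idx], kind="stable")]
    m_sorted = m_idx[np.argsort(flat[m_idx], kind="stable")]
    f_start = np.concatenate([[0], np.cumsum(nf)])[:-1]
    m_start = np.concatenate([[0], np.cumsum(nm)])[:-1]

    cell_per_recruit = np.repeat(cells, recruits)
    lone = ntot[cell_per_recruit] == 1
    mothers = np.empty(total, dtype=np.int64)
    fathers = np.empty(total, dtype=np.int64)
    if lone.any():
        solo = order[starts[cell_per_recruit[lone]]]
        mothers[lone] = solo
        fathers[lone] = solo
    paired = ~lone
    cp = cell_per_recruit[paired]
    mothers[paired] = f_sorted[f_start[cp]
                               + (rng.random(paired.sum()) * nf[cp]).astype(np.int64)]
    fathers[paired] = m_sorted[m_start[cp]
                               + (rng.random(paired.sum()) * nm[cp]).astype(np.int64)]

    pick_m = rng.integers(2, size=(total, loci_count))
    pick_f = rng.integers(2, size=(total, loci_count))
    allele_m = np.take_along_axis(
        state.genotypes[mothers], pick_m[:, :, None], axis=2)[:, :, 0]
    allele_f = np.take_along_axis(
        state.genotypes[fathers], pick_f[:, :, None], axis=2)[:, :, 0]
    genotypes = np.stack([allele_m, allele_f], axis=2).astype(np.int16)
    sex = rng.integers(2, size=total).astype(np.int8)
    row = (cell_per_recruit // nc).astype(np.int16)
    col = (cell_per_recruit % nc).astype(np.int16)
    return row, col, sex, genotypes


def mutate(
    genotypes: np.ndarray,
    loci: list[LocusFrequencyTable],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> int:
    """Mutate allele copies in place; returns the number of mutations.

    Each copy mutates independently with probability ``mutation_rate``. Under
    the default k-allele model a mutation becomes a uniformly chosen
    *different* state from the locus's founder state space; under ``smm`` it
    steps +-1 within the state space. Loci with a single state cannot mutate.
    """
    if config.mutation_rate == 0.0 or genotypes.size == 0:
        return 0
    mask = rng.random(genotypes.shape) < config.mutation_rate
    count = 0
    for j, locus in enumerate(loci):
        k = locus.n_alleles
        hits = np.nonzero(mask[:, j, :])
        m = len(hits[0])
        if m == 0 or k == 1:
            continue
        old = genotypes[:, j, :][hits]
        if config.mutation_model == "kam":
            draw = rng.integers(1, k, size=m)  # offset in 1..k-1
            new = ((old - 1 + draw) % k) + 1
        else:  # single-step, reflecting at the state-space boundary
            step = rng.choice([-1, 1], size=m)
            new = np.clip(old + step, 1, k)
            new = np.where(new == old, old - step, new)
        genotypes[:, j, :][hits] = new.astype(np.int16)
        count += m
    return count


def step(
    state: PopulationState,
    surface: ResistanceSurface,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """One generation: disperse, reproduce, mutate recruits, adults die."""
    state = disperse(state, surface, config, rng)
    row, col, sex, genotypes = reproduce(state, surface, config, rng)
    n_mut = mutate(genotypes, state.loci, config, rng)
    info = dict(state.last_info, mutations=n_mut)
    if len(row) == 0:
        out = _empty_state(state.loci, state.generation + 1, state.replicate)
        out.last_info = info
        return out
    return PopulationState(
        row=row, col=col, sex=sex, genotypes=genotypes, loci=state.loci,
        generation=state.generation + 1, replicate=state.replicate,
        last_info=info,
    )


@dataclass
class ReplicateResult:
    replicate: int
    census: np.ndarray  # per generation 0..G
    census_by_side: np.ndarray  # (G+1, 2)
    snapshots: dict  # generation -> PopulationState
    extinct_at: int | None = None


def run_replicate(
    surface: ResistanceSurface,
    density: str,
    founders: FounderPanel,
    config: SimulationConfig,
    seed,
    replicate: int = 0,
    snapshot_generations=None,
) -> ReplicateResult:
    """Run one replicate, recording census per generation and snapshots."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_seed, run_seed = ss.spawn(2)
    state = initialize_population(surface, density, founders, seed=init_seed)
    state.replicate = replicate
    rng = np.random.default_rng(run_seed)
    G = config.n_generations
    if snapshot_generations is None:
        snapshot_generations = set(range(0, G + 1, config.sample_interval)) | {0, G}
    else:
        snapshot_generations = set(snapshot_generations)

    census = np.zeros(G + 1, dtype=np.int64)
    by_side = np.zeros((G + 1, 2), dtype=np.int64)
    snapshots = {}
    extinct_at = None

    def record(s):
        census[s.generation] = s.n
        if s.n:
            sides = surface.side_of(s.col)
            by_side[s.generation] = np.bincount(sides, minlength=2)
        if s.generation in snapshot_generations and s.n:
            snapshots[s.generation] = s.copy()

    record(state)
    for _ in range(G):
        state = step(state, surface, config, rng)
        record(state)
        if state.n == 0:
            extinct_at = state.generation
            break
    return ReplicateResult(replicate, census, by_side, snapshots, extinct_at)


def run_replicates(
    surface: ResistanceSurface,
    density: str,
    founders: FounderPanel,
    config: SimulationConfig,
    seed,
    snapshot_generations=None,
) -> list[ReplicateResult]:
    """Run ``config.n_replicates`` independent replicates with derived seeds."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(config.n_replicates)
    results = []
    for rep, child in enumerate(children):
        results.append(
            run_replicate(
                surface, density, founders, config, child, replicate=rep,
                snapshot_generations=snapshot_generations,
            )
        )
    return results
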