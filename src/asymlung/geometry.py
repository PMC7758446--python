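"""Generation and alteration of an asymmetric tracheobronchial tree.

The conducting airways are modelled as a rooted binary tree of right
circular cylinders.  Each airway ``(i, j)`` (generation ``i``, index ``j``)
bifurcates into a minor daughter ``(i+1, 2j-1)`` and a major daughter
``(i+1, 2j)``.  Daughter diameters follow generation-dependent scaling
ratios derived from the Hess--Murray law, perturbed by asymmetry
parameters and by a Gaussian anatomical variability whose two daughters
are anti-correlated so that the summed daughter volume is conserved.
An airway becomes terminal when one of its would-be daughters falls at or
below the cutoff diameter ``D_lim`` (twice the alveolus diameter by
default); two identical acini hang from every terminal airway.

Internally the tree is stored as a struct-of-arrays in breadth-first
order, so the flat index of a parent is always smaller than the flat
index of its daughters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeometryParams",
    "LungTree",
    "base_ratios",
    "daughter_ratios",
    "generate_tree",
    "terminal_generation_histogram",
    "select_airways",
    "select_by_diameter",
    "select_terminal_extreme",
    "select_random_fraction",
    "ancestors_of",
    "apply_lumen_alteration",
    "apply_acinar_alteration",
]

_CBRT_HALF = 2.0 ** (-1.0 / 3.0)


@dataclass(frozen=True)
class GeometryParams:
    """Parameters defining the reference lung geometry.

    Per-generation sequences (``alpha``, ``chi_min``, ``chi_maj``,
    ``sigma``) are extended beyond their last entry: generation indices
    past the end of a sequence reuse its final value.

    Units are SI throughout (metres, cubic metres).
    """

    tracheal_diameter: float = 1.5e-2
    tracheal_length: float = 12e-2
    #: length-to-diameter aspect ratio per generation (airway's own generation)
    alpha: Sequence[float] = (8.00, 3.07, 1.75, 1.43, 1.85, 3.00)
    #: asymmetry parameter of the minor daughter, indexed by parent generation
    chi_min: Sequence[float] = (0.10, 0.12, 0.12, 0.05, 0.12, 0.12)
    #: asymmetry parameter of the major daughter, indexed by parent generation
    chi_maj: Sequence[float] = (0.08, 0.01, 0.04, 0.07, 0.08, 0.08)
    #: dispersion of the minor diameter ratio, indexed by parent generation
    sigma: Sequence[float] = (0.0, 0.0, 0.0, 0.0, 0.05, 0.05)
    #: alveolus inner diameter
    d_alv: float = 200e-6
    #: terminal cutoff diameter; ``None`` defaults to ``2 * d_alv``
    d_lim: float | None = None
    #: acinar airway length and diameter (identical in all 7 acinar generations)
    acinar_length: float = 1e-3
    acinar_diameter: float = 400e-6
    #: alveoli per acinar airway, generations 1..7
    n_alv: Sequence[int] = (12, 26, 42, 87, 102, 123, 123)
    #: oropharyngeal + laryngeal cavity volume (m^3)
    cavity_volume: float = 106e-6
    #: reference wall-layer thicknesses assigned to every generated airway
    delta_mu: float = 10e-6
    delta_e: float = 10e-6
    delta_m: float = 30e-6
    max_generations: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tracheal_diameter", "tracheal_length", "d_alv",
                     "acinar_length", "acinar_diameter", "cavity_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(s < 0 for s in self.sigma):
            raise ValueError("sigma values must be non-negative")
        if any(c < 0 for c in self.chi_min) or any(c < 0 for c in self.chi_maj):
            raise ValueError("asymmetry parameters must be non-negative")
        if len(self.n_alv) != 7:
            raise ValueError("n_alv must list the 7 acinar generations")

    @property
    def cutoff_diameter(self) -> float:
        return 2.0 * self.d_alv if self.d_lim is None else self.d_lim

    def per_generation(self, name: str, i: int) -> float:
        """Value of a per-generation parameter at generation ``i`` (1-based)."""
        seq = getattr(self, name)
        return float(seq[min(i, len(seq)) - 1])


@dataclass
class LungTree:
    """The generated airway forest, in breadth-first (parent-first) order.

    All arrays have length ``n_airw``.  ``children[k]`` holds the flat
    indices of the minor and major daughters of airway ``k`` (or -1 for a
    terminal airway).  ``phi`` and ``gamma`` are only meaningful on
    terminal airways (acinar linear-reduction and perfusion factors).
    """

    generation: np.ndarray
    index: np.ndarray
    parent: np.ndarray
    child_minor: np.ndarray
    child_major: np.ndarray
    diameter: np.ndarray
    length: np.ndarray
    delta_mu: np.ndarray
    delta_e: np.ndarray
    delta_m: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    params: GeometryParams
    seed: int
    redraws: int = 0

    @property
    def n_airw(self) -> int:
        return self.diameter.size

    @property
    def terminal(self) -> np.ndarray:
        return self.child_minor < 0

    @property
    def terminal_ids(self) -> np.ndarray:
        return np.flatnonzero(self.terminal)

    @property
    def n_term(self) -> int:
        return int(self.terminal.sum())

    def copy(self) -> "LungTree":
        arrays = {
            name: getattr(self, name).copy()
            for name in ("generation", "index", "parent", "child_minor",
                         "child_major", "diameter", "length", "delta_mu",
                         "delta_e", "delta_m", "phi", "gamma")
        }
        return replace(self, **arrays)

    def validate(self) -> None:
        if self.n_airw != 2 * self.n_term - 1:
            raise AssertionError("binary-tree identity n_airw = 2 n_term - 1 violated")
        inner = ~self.terminal
        if np.any(self.diameter[self.child_minor[inner]] >= self.diameter[inner]):
            raise AssertionError("a daughter diameter is not smaller than its parent")
        if np.any(self.diameter[self.child_major[inner]] >= self.diameter[inner]):
            raise AssertionError("a daughter diameter is not smaller than its parent")


def base_ratios(chi_min: float, chi_maj: float) -> tuple[float, float]:
    """Diameter scaling ratios of the minor and major daughters.

    With both asymmetry parameters zero the ratios reduce to the
    Hess--Murray value ``2**(-1/3)``.
    """
    if chi_min < 0 or chi_maj < 0:
        raise ValueError("asymmetry parameters must be non-negative")
    h_min = 2.0 ** (-1.0 / 3.0 - chi_min)
    h_maj = 2.0 ** (-1.0 / 3.0 + chi_maj)
    if h_maj >= 1.0 or h_min >= 1.0:
        raise ValueError("asymmetry parameter yields a daughter at least as wide as its parent")
    return h_min, h_maj


def daughter_ratios(
    h0_min: float,
    h0_maj: float,
    sigma: float,
    x: float,
) -> tuple[float, float]:
    """Randomized daughter ratios conserving the summed daughter volume.

    ``x`` is a standard-normal draw; the minor ratio is shifted by
    ``sigma * x`` and the major ratio is adjusted so that
    ``h_min**3 + h_maj**3`` is unchanged.
    """
    if not (0.0 < h0_min <= h0_maj < 1.0):
        raise ValueError("require 0 < h0_min <= h0_maj < 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    h_min = h0_min + sigma * x
    cube = h0_maj**3 + h0_min**3 - h_min**3
    if h_min <= 0.0 or h_min >= 1.0 or cube <= 0.0:
        raise ValueError("randomized ratio outside (0, 1); redraw")
    h_maj = cube ** (1.0 / 3.0)
    if h_maj >= 1.0:
        raise ValueError("randomized ratio outside (0, 1); redraw")
    return h_min, h_maj


def _draw_ratios(
    h0_min: float, h0_maj: float, sigma: float, rng: np.random.Generator,
    max_redraws: int = 1000,
) -> tuple[float, float, int]:
    """Rejection-sample valid daughter ratios; counts redraws."""
    if sigma == 0.0:
        return h0_min, h0_maj, 0
    for attempt in range(max_redraws):
        try:
            h_min, h_maj = daughter_ratios(h0_min, h0_maj, sigma, rng.standard_normal())
        except ValueError:
            continue
        return h_min, h_maj, attempt
    raise RuntimeError("could not draw valid daughter ratios; sigma too large?")


def generate_tree(params: GeometryParams) -> LungTree:
    """Generate the stochastic asymmetric tracheobronchial tree.

    The single seeded generator is consumed in breadth-first airway
    order, so a fixed seed reproduces the geometry bit-for-bit and
    later alterations never perturb it.
    """
    rng = np.random.Generator(np.random.PCG64(params.seed))
    d_lim = params.cutoff_diameter

    gen = [1]
    idx = [1]
    par = [-1]
    diam = [params.tracheal_diameter]
    leng = [params.tracheal_length]
    child_minor = [-1]
    child_major = [-1]
    redraws = 0

    head = 0
    while head < len(diam):
        i, j, d = gen[head], idx[head], diam[head]
        if i >= params.max_generations:
            raise RuntimeError(
                f"tree generation exceeded {params.max_generations} generations; "
                "check the geometry parameters"
            )
        h0_min, h0_maj = base_ratios(
            params.per_generation("chi_min", i), params.per_generation("chi_maj", i)
        )
        h_min, h_maj, n_re = _draw_ratios(
            h0_min, h0_maj, params.per_generation("sigma", i), rng
        )
        redraws += n_re
        d_minor, d_major = h_min * d, h_maj * d
        if min(d_minor, d_major) <= d_lim:
            head += 1
            continue  # airway stays terminal; daughters are not created
        alpha_next = params.per_generation("alpha", i + 1)
        child_minor[head] = len(diam)
        child_major[head] = len(diam) + 1
        for dd, jj in ((d_minor, 2 * j - 1), (d_major, 2 * j)):
            gen.append(i + 1)
            idx.append(jj)
            par.append(head)
            diam.append(dd)
            leng.append(alpha_next * dd)
            child_minor.append(-1)
            child_major.append(-1)
        head += 1

    n = len(diam)
    tree = LungTree(
        generation=np.asarray(gen, dtype=np.int64),
        index=np.asarray(idx, dtype=np.int64),
        parent=np.asarray(par, dtype=np.int64),
        child_minor=np.asarray(child_minor, dtype=np.int64),
        child_major=np.asarray(child_major, dtype=np.int64),
        diameter=np.asarray(diam, dtype=float),
        length=np.asarray(leng, dtype=float),
        delta_mu=np.full(n, params.delta_mu),
        delta_e=np.full(n, params.delta_e),
        delta_m=np.full(n, params.delta_m),
        phi=np.ones(n),
        gamma=np.ones(n),
        params=params,
        seed=params.seed,
        redraws=redraws,
    )
    tree.validate()
    return tree


def terminal_generation_histogram(tree: LungTree) -> tuple[np.ndarray, np.ndarray]:
    """Probability distribution of the terminal-airway generation index.

    Returns ``(generations, probabilities)`` with probabilities summing
    to one.
    """
    gens = tree.generation[tree.terminal]
    values, counts = np.unique(gens, return_counts=True)
    return values, counts / counts.sum()


# ---------------------------------------------------------------------------
# airway selection


def select_by_diameter(tree: LungTree, d_max: float) -> np.ndarray:
    """Flat ids of airways with lumen diameter strictly below ``d_max``."""
    return np.flatnonzero(tree.diameter < d_max)


def _terminals_sorted_by_depth(tree: LungTree) -> np.ndarray:
    term = tree.terminal_ids
    order = np.lexsort((tree.index[term], tree.generation[term]))
    return term[order]


def select_terminal_extreme(tree: LungTree, fraction: float, which: str) -> np.ndarray:
    """The ``fraction`` of terminals nearest to / farthest from the trachea.

    Terminals are ordered by generation index (path length from the
    trachea), ties broken by the within-generation index ``j``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    ordered = _terminals_sorted_by_depth(tree)
    k = int(round(fraction * ordered.size))
    if which == "nearest":
        return np.sort(ordered[:k])
    if which == "farthest":
        return np.sort(ordered[ordered.size - k:])
    raise ValueError(f"unknown extreme {which!r}")


def select_random_fraction(
    tree: LungTree,
    fraction: float,
    seed: int,
    pool: np.ndarray | None = None,
) -> np.ndarray:
    """A seeded random ``fraction`` of ``pool`` (default: the terminals)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    pool = tree.terminal_ids if pool is None else np.asarray(pool)
    rng = np.random.Generator(np.random.PCG64(seed))
    k = int(round(fraction * pool.size))
    return np.sort(rng.choice(pool, size=k, replace=False))


def ancestors_of(tree: LungTree, ids: Iterable[int], k: int) -> np.ndarray:
    """Union of the 1..k-step ancestors of ``ids`` (deduplicated)."""
    out: set[int] = set()
    for a in np.asarray(list(ids), dtype=np.int64):
        p = tree.parent[a]
        for _ in range(k):
            if p < 0:
                break
            out.add(int(p))
            p = tree.parent[p]
    return np.asarray(sorted(out), dtype=np.int64)


def select_airways(tree: LungTree, criterion: dict) -> np.ndarray:
    """Dispatch airway selection from a serializable criterion mapping.

    Supported kinds: ``diameter_below`` (``d_max``), ``terminal_extreme``
    (``fraction``, ``which``), ``random_fraction`` (``fraction``, ``seed``,
    optional ``small_airways_below``), ``explicit`` (``ids``) and
    ``ancestors`` (``of`` criterion, ``k`` generations, ``include_base``).
    """
    kind = criterion.get("kind")
    if kind == "diameter_below":
        return select_by_diameter(tree, criterion["d_max"])
    if kind == "terminal_extreme":
        return select_terminal_extreme(tree, criterion["fraction"], criterion["which"])
    if kind == "random_fraction":
        pool = None
        if "small_airways_below" in criterion:
            pool = select_by_diameter(tree, criterion["small_airways_below"])
        return select_random_fraction(tree, criterion["fraction"], criterion["seed"], pool)
    if kind == "explicit":
        return np.asarray(criterion["ids"], dtype=np.int64)
    if kind == "ancestors":
        base = select_airways(tree, criterion["of"])
        anc = ancestors_of(tree, base, criterion["k"])
        if criterion.get("include_base", True):
            anc = np.union1d(anc, base)
        return anc
    raise ValueError(f"unknown selection criterion {kind!r}")


# ---------------------------------------------------------------------------
# structural alterations


def apply_lumen_alteration(
    tree: LungTree,
    ids: Iterable[int],
    beta: float,
    mode: str,
) -> LungTree:
    """Narrow the lumen of selected airways by the area-reduction factor ``beta``.

    The altered diameter satisfies ``D' = D * sqrt(1 - beta)``.  In
    ``liquid`` mode the freed annulus is filled by the liquid layer only
    (mucus accumulation); epithelium and muscle are untouched.  In
    ``muscle`` mode (smooth-muscle contraction) every layer keeps its
    annular cross-sectional area, so all three thicknesses grow as the
    layers are squeezed inward.  Applying an alteration twice composes.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must be in [0, 1)")
    ids = np.asarray(list(ids) if not isinstance(ids, np.ndarray) else ids, dtype=np.int64)
    out = tree.copy()
    if ids.size == 0 or beta == 0.0:
        return out
    d_old = out.diameter[ids]
    d_new = d_old * np.sqrt(1.0 - beta)
    if mode == "liquid":
        out.delta_mu[ids] = out.delta_mu[ids] + (d_old - d_new) / 2.0
    elif mode == "muscle":
        r0 = d_old / 2.0
        r0_new = d_new / 2.0
        r_prev, r_prev_new = r0, r0_new
        for layer in ("delta_mu", "delta_e", "delta_m"):
            arr = getattr(out, layer)
            r_k = r_prev + arr[ids]
            r_k_new = np.sqrt(r_prev_new**2 + (r_k**2 - r_prev**2))
            arr[ids] = r_k_new - r_prev_new
            r_prev, r_prev_new = r_k, r_k_new
    else:
        raise ValueError(f"unknown alteration mode {mode!r}")
    out.diameter[ids] = d_new
    return out


def apply_acinar_alteration(
    tree: LungTree,
    ids: Iterable[int],
    phi: float | None = None,
    gamma: float | None = None,
) -> LungTree:
    """Set the acinar reduction factor and/or perfusion coefficient.

    ``phi`` scales the linear dimensions of the two acini attached to a
    terminal airway (it enters the flow resistance as ``phi**3`` and the
    terminal transport boundary condition as ``phi**2``); ``gamma``
    scales the alveolar uptake of the species.  Only terminal airways
    may be altered.
    """
    ids = np.asarray(list(ids) if not isinstance(ids, np.ndarray) else ids, dtype=np.int64)
    if np.any(~tree.terminal[ids]):
        raise ValueError("acinar alterations apply to terminal airways only")
    if phi is not None and not 0.0 < phi <= 1.0:
        raise ValueError("phi must be in (0, 1]; use a small positive value for blockage")
    if gamma is not None and not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    out = tree.copy()
    if phi is not None:
        out.phi[ids] = phi
    if gamma is not None:
        out.gamma[ids] = gamma
    return out
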