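"""Scenario presets, Morris sensitivity screening and stochasticity studies.

The presets bundle the published input settings for the stochastic-effects
study (chorionic vessels), the whole-organ build, and the three placentone
cases (healthy, spiral-artery mega jet, fetal growth restriction).  The FGR
case encodes reduced volume/thickness/placentone count, a 20% thinner stem,
a 20% wider mean branching angle and a lower bifurcation exponent.

Sensitivity uses the Morris elementary-effects method: Latin-hypercube
seeded randomized one-at-a-time trajectories over a unit input box, with
μ* (mean |EE|) measuring influence and σ (sd of EE) interactions; inputs
are ranked by the cost function 0.5·μ*_norm + 0.5·(1 − σ_norm).
Run-to-run variability is quantified by the closed-form KL divergence
between per-run Gaussian fits of each output metric.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from . import density, geometry, trees, villous
from .chorionic import grow_chorionic_tree
from .config import Distribution, normal, uniform
from .geometry import PlacentalShapeParams, build_placentone
from .villous import VillousGrowthParams, default_stem, grow_villous_tree

logger = logging.getLogger("fetovasc.experiments")


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    shape: dict = field(default_factory=dict)
    chorionic: dict = field(default_factory=dict)
    placentone: dict = field(default_factory=dict)
    villous: dict = field(default_factory=dict)

    def villous_params(self, **overrides) -> VillousGrowthParams:
        return VillousGrowthParams.from_dict({**self.villous, **overrides})

    def to_yaml(self) -> str:
        def enc(d):
            return {k: (v.to_spec() if isinstance(v, Distribution) else v)
                    for k, v in d.items()}
        return yaml.safe_dump({"name": self.name, "shape": enc(self.shape),
                               "chorionic": enc(self.chorionic),
                               "placentone": enc(self.placentone),
                               "villous": enc(self.villous)}, sort_keys=True)


_SHAPE_POPULATION = {
    "V": uniform(400.0, 500.0),
    "r_maj": normal(9.3, 0.455),
    "E": normal(0.49, 0.17),
    "CCI": normal(0.36, 0.21),
    "m_t": 20.0,
}

_VILLOUS_HEALTHY = {
    "d_s": normal(0.7, 0.03), "ltd_v": normal(10.5, 0.8), "k_v": 3.2,
    "a": normal(1.0, 0.05), "theta_pd": normal(45.0, 15.0),
    "theta_dd_min": 25.0, "cf1": 0.7, "cf2": 0.3, "bg_v": 15,
}

PRESETS: dict[str, ScenarioPreset] = {
    "chorionic-stochastic": ScenarioPreset(
        name="chorionic-stochastic", shape=dict(_SHAPE_POPULATION),
        chorionic={}),  # chorionic defaults are the published settings
    "whole-organ": ScenarioPreset(
        name="whole-organ", shape=dict(_SHAPE_POPULATION), chorionic={},
        villous={**_VILLOUS_HEALTHY, "bg_v": 13}),
    "healthy-placentone": ScenarioPreset(
        name="healthy-placentone",
        placentone={"V": 390.0, "thickness": 24.0, "n_p": 65,
                    "CC_r": 1.88, "CC_h": 5.6},
        villous=dict(_VILLOUS_HEALTHY)),
    "sa-mega-jet-placentone": ScenarioPreset(
        name="sa-mega-jet-placentone",
        placentone={"V": 390.0, "thickness": 24.0, "n_p": 65,
                    "CC_r": 1.88, "CC_h": 12.91},
        villous=dict(_VILLOUS_HEALTHY)),
    "fgr-placentone": ScenarioPreset(
        name="fgr-placentone",
        placentone={"V": 292.5, "thickness": 18.0, "n_p": 42,
                    "CC_r": 1.88, "CC_h": 5.6},
        villous={**_VILLOUS_HEALTHY, "d_s": normal(0.56, 0.03), "k_v": 2.8,
                 "theta_pd": normal(54.0, 15.0)}),
}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"known: {sorted(PRESETS)}") from None


def preset_hash(name: str) -> str:
    return hashlib.sha256(get_preset(name).to_yaml().encode()).hexdigest()[:12]


def run_placentone(preset: ScenarioPreset | str, rng_seed=None,
                   **villous_overrides):
    """Build the preset's placentone and grow one villous tree in it."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    rng = np.random.default_rng(rng_seed)
    dom = build_placentone(**preset.placentone)
    params = preset.villous_params(**villous_overrides)
    tree = grow_villous_tree(dom, default_stem(dom, params, rng), params, rng)
    return tree, dom


def run_chorionic(preset: ScenarioPreset | str = "chorionic-stochastic",
                  rng_seed=None, seed_density: float = 13.0,
                  chorionic_overrides: dict | None = None, cci=None):
    """Sample a placental shape, extract the plate and grow a chorionic tree."""
    from .chorionic import ChorionicGrowthParams
    if isinstance(preset, str):
        preset = get_preset(preset)
    rng = np.random.default_rng(rng_seed)

    def draw(key, default=None):
        v = preset.shape.get(key, default)
        v = Distribution.from_spec(v)
        return float(v.sample(rng))

    shape = PlacentalShapeParams(
        V=draw("V"), r_maj=draw("r_maj"),
        E=float(np.clip(draw("E"), 0.0, 0.95)),
        CCI=float(np.clip(draw("CCI") if cci is None else cci, 0.0, 1.0)),
        m_t=draw("m_t"))
    surface = geometry.build_placental_surface(shape, target_seed_density=seed_density,
                                               refine=False)
    a_chor = geometry.chorionic_area(shape.r_maj, shape.r_min, shape.t_half)
    plate = geometry.extract_chorionic_plate(surface, a_chor)
    insertion = geometry.locate_cord_insertion(plate, shape.CCI, shape.r_maj,
                                               shape.m_t, rng)
    params = ChorionicGrowthParams.from_dict({**preset.chorionic,
                                              **(chorionic_overrides or {})})
    tree = grow_chorionic_tree(plate, insertion, params, rng)
    return tree, plate, shape


# ---------------------------------------------------------------------------
# Morris elementary-effects screening
# ---------------------------------------------------------------------------

@dataclass
class MorrisResult:
    """μ*/σ of elementary effects per (input, output), on unit-scaled inputs."""

    inputs: list
    outputs: list
    mu_star: np.ndarray   # (n_inputs, n_outputs)
    sigma: np.ndarray
    n_trajectories: int
    n_levels: int

    def normalized(self):
        """Min-max normalise μ* and σ across inputs, per output."""
        def nm(m):
            lo = m.min(axis=0, keepdims=True)
            hi = m.max(axis=0, keepdims=True)
            rng_ = np.where(hi - lo > 0, hi - lo, 1.0)
            return (m - lo) / rng_
        return nm(self.mu_star), nm(self.sigma)

    def scores(self) -> np.ndarray:
        mu_n, sg_n = self.normalized()
        return morris_score(mu_n, sg_n)

    def top_inputs(self, output: str, n: int = 3) -> list:
        j = self.outputs.index(output)
        order = np.argsort(-self.scores()[:, j])
        return [self.inputs[i] for i in order[:n]]

    def to_dataframe(self) -> pd.DataFrame:
        mu_n, sg_n = self.normalized()
        sc = self.scores()
        rows = []
        for j, out in enumerate(self.outputs):
            rank = np.argsort(np.argsort(-sc[:, j]))
            for i, inp in enumerate(self.inputs):
                rows.append({"input": inp, "output": out,
                             "mu_star": self.mu_star[i, j],
                             "sigma": self.sigma[i, j],
                             "mu_star_norm": mu_n[i, j],
                             "sigma_norm": sg_n[i, j],
                             "score": sc[i, j], "rank": int(rank[i]) + 1,
                             "highly_influential": bool(rank[i] < 3)})
        return pd.DataFrame(rows)


def morris_score(mu_star_norm, sigma_norm):
    """Cost 0.5·μ* + 0.5·(1 − σ) on inputs normalised to [0, 1]."""
    mu = np.asarray(mu_star_norm, dtype=float)
    sg = np.asarray(sigma_norm, dtype=float)
    return 0.5 * mu + 0.5 * (1.0 - sg)


def morris_screen(model, ranges: dict, samples_per_param: int,
                  rng_seed=None, n_levels: int = 4) -> MorrisResult:
    """Randomized one-at-a-time elementary-effects screening.

    ``model`` maps a dict of input values to a dict of output metrics;
    ``ranges`` maps input names to (lo, hi).  Inputs are scaled to [0, 1]
    over their ranges so μ* is comparable across inputs.  Base points are
    Latin-hypercube seeded on the Morris grid; each of the
    ``samples_per_param`` trajectories perturbs every input once by
    Δ = p/(2(p−1)).  Failed model evaluations are skipped and logged; the
    surviving steps of the trajectory are kept.
    """
    rng = np.random.default_rng(rng_seed)
    names = list(ranges)
    k = len(names)
    p = n_levels
    delta = p / (2.0 * (p - 1.0))
    base_levels = np.array([i / (p - 1.0) for i in range(p)
                            if i / (p - 1.0) <= 1.0 - delta + 1e-12])
    lhs = qmc.LatinHypercube(d=k, seed=rng).random(samples_per_param)
    base = base_levels[np.minimum((lhs * base_levels.size).astype(int),
                                  base_levels.size - 1)]

    lo = np.array([ranges[n][0] for n in names], dtype=float)
    hi = np.array([ranges[n][1] for n in names], dtype=float)

    def evaluate(x_unit):
        x = lo + x_unit * (hi - lo)
        try:
            return dict(model(dict(zip(names, x))))
        except Exception as exc:  # model failure: skip this point
            logger.warning("model failed at %s: %s", dict(zip(names, x)), exc)
            return None

    ee: dict[tuple, list] = {}
    outputs: list = []
    for t in range(samples_per_param):
        x = base[t].copy()
        flip = rng.random(k) < 0.5  # pre-flip for direction randomization
        x[flip] = 1.0 - delta - x[flip]
        order = rng.permutation(k)
        points = [x.copy()]
        signs = []
        for i in order:
            x = x.copy()
            sign = -1.0 if flip[i] else 1.0
            x[i] += sign * delta
            points.append(x.copy())
            signs.append(sign)
        values = [evaluate(pt) for pt in points]
        for step, i in enumerate(order):
            f0, f1 = values[step], values[step + 1]
            if f0 is None or f1 is None:
                continue
            for out in f0:
                if out not in outputs:
                    outputs.append(out)
                e = (f1[out] - f0[out]) / (signs[step] * delta)
                if np.isfinite(e):
                    ee.setdefault((names[i], out), []).append(e)

    mu_star = np.zeros((k, len(outputs)))
    sigma = np.zeros((k, len(outputs)))
    for i, name in enumerate(names):
        for j, out in enumerate(outputs):
            es = np.asarray(ee.get((name, out), []), dtype=float)
            if es.size:
                mu_star[i, j] = np.mean(np.abs(es))
                sigma[i, j] = np.std(es, ddof=1) if es.size > 1 else 0.0
    return MorrisResult(names, outputs, mu_star, sigma,
                        samples_per_param, n_levels)


# ---------------------------------------------------------------------------
# KL stochasticity
# ---------------------------------------------------------------------------

def kl_divergence_gaussian(mu1, sigma1, mu2, sigma2) -> float:
    """KL(N(μ1,σ1) ‖ N(μ2,σ2)) in closed form; non-negative."""
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("standard deviations must be positive")
    return (math.log(sigma2 / sigma1)
            + (sigma1 ** 2 + (mu1 - mu2) ** 2) / (2.0 * sigma2 ** 2) - 0.5)


def _terminal_generations(tree):
    term = tree.terminal_segments()
    return trees.bifurcation_generations(tree)[term].astype(float)


#: per-tree sample arrays for Gaussian fits of output metrics
TREE_METRICS = {
    "path_length": trees.path_lengths,
    "branching_angle": trees._branching_angles,
    "terminal_diameter": lambda t: t.segment_diameters[t.terminal_segments()],
    "terminal_length": lambda t: t.segment_lengths()[t.terminal_segments()],
    "ltd": lambda t: (t.segment_lengths()[t.segments]
                      / t.segment_diameters[t.segments]),
    "branching_generations": _terminal_generations,
}


# ---------------------------------------------------------------------------
# reproduction studies (placentone cases, insertion comparison, scaled organ)
# ---------------------------------------------------------------------------

def placentone_case_study(preset: ScenarioPreset | str, n_runs: int,
                          rng_seed=None, **villous_overrides) -> pd.DataFrame:
    """Per-run key metrics for one placentone scenario.

    Columns: mean stem-to-terminal path length (mm, stem included), mean
    vascular density (%), mean terminal diameter (mm), Strahler branching
    ratio and segment count.
    """
    seeds = np.random.SeedSequence(rng_seed).spawn(n_runs)
    rows = []
    for ss in seeds:
        tree, dom = run_placentone(preset, np.random.default_rng(ss),
                                   **villous_overrides)
        term = tree.terminal_segments()
        try:
            s_b, _, _ = trees.strahler_ratios(tree)
        except trees.TreeError:
            s_b = float("nan")
        rows.append({
            "mean_path_length_mm": float(trees.path_lengths(tree).mean()),
            "mean_vascular_density_pct": density.mean_vascular_density(
                tree, dom.volume),
            "mean_terminal_diameter_mm": float(
                tree.segment_diameters[term].mean()),
            "strahler_branching_ratio": s_b,
            "segment_count": tree.n_segments,
        })
    return pd.DataFrame(rows)


def chorionic_generation_study(n_runs: int, rng_seed=None, central: bool = True,
                               seed_density: float = 13.0,
                               min_noncentral_cci: float = 0.15) -> pd.DataFrame:
    """Mean chorionic branching generations for central / non-central cords.

    Central runs pin CCI at 0; non-central runs sample the population CCI
    distribution truncated away from the centroid.  The generation count is
    the mean bifurcation level over all segments.
    """
    from .chorionic import GrowthFailure
    seeds = np.random.SeedSequence(rng_seed).spawn(4 * n_runs)
    rows = []
    attempt = iter(seeds)
    while len(rows) < n_runs:
        rng = np.random.default_rng(next(attempt))
        cci = 0.0
        if not central:
            while True:
                cci = float(np.clip(rng.normal(0.36, 0.21), 0.0, 0.95))
                if cci >= min_noncentral_cci:
                    break
        try:
            tree, _, shape = run_chorionic(rng_seed=rng,
                                           seed_density=seed_density, cci=cci)
        except GrowthFailure as exc:  # degenerate shape draw: replace the run
            logger.warning("chorionic run failed (%s); resampling", exc)
            continue
        gens = trees.bifurcation_generations(tree)[tree.segments]
        rows.append({"cci": shape.CCI,
                     "mean_branching_generations": float(gens.mean()),
                     "segment_count": tree.n_segments,
                     "max_generation": int(
                         tree.segment_generation[tree.segments].max())})
    return pd.DataFrame(rows)


def _column_density_profile(tree, shape, n_bins: int = 12):
    """Z-averaged vascular density per in-plane column, binned by the
    normalized elliptical radius ρ = sqrt((x/a)² + (y/b)²)."""
    a = shape.r_maj * 10.0
    b = shape.r_min * 10.0
    segs = tree.segments
    mids = 0.5 * (tree.node_coords[segs] + tree.node_coords[tree.parent_index[segs]])
    lengths = tree.segment_lengths()[segs]
    vols = 2.125 * np.pi * (tree.segment_diameters[segs] / 2.0) ** 2 * lengths
    rho = np.sqrt((mids[:, 0] / a) ** 2 + (mids[:, 1] / b) ** 2)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(rho, edges) - 1, 0, n_bins - 1)
    vol_per_bin = np.bincount(idx, weights=vols, minlength=n_bins)
    # column volume over the full z-extent (the z-averaged-map denominator)
    ring_area = np.pi * a * b * np.diff(edges ** 2)
    height = 2.0 * shape.t_half * 10.0
    return edges, 100.0 * vol_per_bin / (ring_area * height)


def scaled_full_build_study(rng_seed=None, bg_v: int = 5,
                            seed_density: float = 13.0,
                            n_runs_per_case: int = 3,
                            noncentral_cci: float = 0.55) -> dict:
    """Directional whole-organ checks on a scaled-down build.

    Returns the interior/peripheral z-averaged densities (interior ρ < 0.7)
    and the umbilical arterial-supply asymmetry (dominant-artery volume
    fraction) for centralized and non-central cord insertions.  Each central
    / non-central pair shares its random stream (common random numbers), so
    the insertion effect is not swamped by run-to-run growth noise.
    """
    from .villous import VillousGrowthParams, grow_full_vasculature
    seeds = np.random.SeedSequence(rng_seed).spawn(n_runs_per_case)
    out: dict = {"interior_density_pct": [], "peripheral_density_pct": [],
                 "asymmetry": {"central": [], "non_central": []}}
    for ss in seeds:
        for central in (True, False):
            rng = np.random.default_rng(ss)
            cci = 0.0 if central else noncentral_cci
            shape = PlacentalShapeParams(V=450.0, r_maj=9.3, E=0.49, CCI=cci)
            tree = grow_full_vasculature(shape, None,
                                         VillousGrowthParams(bg_v=bg_v),
                                         rng, seed_density=seed_density)
            edges, profile = _column_density_profile(tree, shape)
            centers = 0.5 * (edges[:-1] + edges[1:])
            out["interior_density_pct"].append(float(profile[centers < 0.7].mean()))
            out["peripheral_density_pct"].append(
                float(profile[centers >= 0.7].mean()))
            out["asymmetry"]["central" if central else "non_central"].append(
                umbilical_supply_asymmetry(tree))
    return out


def umbilical_supply_asymmetry(tree) -> float:
    """Fraction of arterial volume fed by the dominant umbilical artery."""
    roots = tree.roots
    par = tree.parent_index
    # assign every node to its root by walking the depth ordering
    owner = np.full(tree.n_nodes, -1, dtype=int)
    owner[roots] = np.arange(roots.size)
    order = np.argsort(trees.node_depths(par), kind="stable")
    for i in order:
        if par[i] != trees.ROOT:
            owner[i] = owner[par[i]]
    segs = tree.segments
    lengths = tree.segment_lengths()[segs]
    vols = np.pi * (tree.segment_diameters[segs] / 2.0) ** 2 * lengths
    per_root = np.bincount(owner[segs], weights=vols, minlength=roots.size)
    return float(per_root.max() / per_root.sum())


def bootstrap_strahler_ratio(tree, n_boot: int = 64, rng=None) -> np.ndarray:
    """Bootstrap samples of the Strahler branching ratio over segments."""
    rng = np.random.default_rng(rng)
    orders = trees.strahler_orders(tree)[tree.segments]
    out = []
    for _ in range(n_boot):
        sample = rng.choice(orders, size=orders.size, replace=True)
        uniq, counts = np.unique(sample, return_counts=True)
        if uniq.size < 2:
            continue
        slope = np.polyfit(uniq.astype(float), np.log10(counts), 1)[0]
        out.append(10.0 ** abs(slope))
    return np.asarray(out)


def stochasticity_study(preset, n_runs: int, metrics=None, rng_seed=None,
                        second_preset=None, **run_overrides) -> pd.DataFrame:
    """Pairwise KL divergences of Gaussian-fitted metrics over seeded runs.

    Each run grows one placentone villous tree; each metric's within-tree
    values are fitted by a univariate Gaussian and all unordered run pairs
    are compared (n(n−1)/2 KL values per metric).  With ``second_preset``
    the pairs are taken across the two presets instead (n² values).
    Degenerate fits (zero variance) are skipped and logged.
    """
    if n_runs < 2:
        raise ValueError("need at least two runs")
    metrics = metrics or list(TREE_METRICS)
    seeds = np.random.SeedSequence(rng_seed).spawn(2 * n_runs)

    def fits(preset_, seed_batch):
        rows = []
        for ss in seed_batch:
            tree, _ = run_placentone(preset_, np.random.default_rng(ss),
                                     **run_overrides)
            fit = {}
            for m in metrics:
                vals = np.asarray(TREE_METRICS[m](tree), dtype=float)
                vals = vals[np.isfinite(vals)]
                if vals.size >= 2 and np.std(vals) > 0:
                    fit[m] = (float(np.mean(vals)), float(np.std(vals)))
            rows.append(fit)
        return rows

    fits_a = fits(preset, seeds[:n_runs])
    records = []
    if second_preset is None:
        pairs = itertools.combinations(range(n_runs), 2)
        fits_b = fits_a
    else:
        fits_b = fits(second_preset, seeds[n_runs:])
        pairs = itertools.product(range(n_runs), range(n_runs))
    for i, j in pairs:
        for m in metrics:
            if m not in fits_a[i] or m not in fits_b[j]:
                logger.info("degenerate %s in pair (%d, %d); skipped", m, i, j)
                continue
            kl = kl_divergence_gaussian(*fits_a[i][m], *fits_b[j][m])
            records.append({"metric": m, "run_i": i, "run_j": j, "kl": kl})
    return pd.DataFrame(records)
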