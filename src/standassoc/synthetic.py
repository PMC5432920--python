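"""Seeded synthetic stem-map generator with known ground truth.

No field census ships with this package, so every analysis stage is
exercised on simulated stands whose spatial pattern, diameter structure and
pairwise association structure are known by construction:

* point patterns — homogeneous Poisson (random), Thomas cluster (clumped),
  sequential-inhibition (regular);
* diameters — a reverse-J mixture of truncated exponentials over the three
  development-stage intervals;
* pairwise association — species pairs share (positive) or avoid
  (negative) a common habitat-patch region, so co-occurrence structure and
  spatial structure stay mutually consistent.

The default community emulates a 0.98 ha old-growth mixed stand: ~870
stems, eleven dominant species with the observed density ranking plus a
tail of minor species, and a juvenile share of ~41 %.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .stemmap import DEFAULT_STAGE_BREAKS, PlotGeometry, StemMap

PatternName = Literal["poisson", "cluster", "inhibition"]

#: Default development-stage mixture (juvenile, medium, large): a reverse-J
#: diameter structure with ~41 % juveniles.
DEFAULT_STAGE_MIX = (0.413, 0.400, 0.187)

#: Exponential decay scales (cm) of the within-stage DBH distributions.
STAGE_DBH_SCALES = (3.0, 7.0, 12.0)

#: Upper DBH cap (cm) for the open-ended large stage.
DBH_CAP = 90.0


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _label_stream(seed: int, *labels: str) -> np.random.Generator:
    """Independent per-label substream: keyed by (seed, labels) so adding a
    species to a community never perturbs the points of existing ones."""
    digest = hashlib.blake2b("/".join(labels).encode(), digest_size=8).digest()
    key = int.from_bytes(digest, "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# point patterns
# ---------------------------------------------------------------------------

def simulate_poisson(
    intensity: float, geometry: PlotGeometry, seed_or_rng
) -> np.ndarray:
    """Homogeneous Poisson pattern: count ~ Poisson(intensity * area),
    positions uniform.  ``intensity`` is trees per m^2."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    rng = _rng(seed_or_rng)
    n = rng.poisson(intensity * geometry.area_m2)
    return rng.uniform((0, 0), (geometry.width, geometry.height), size=(n, 2))


def simulate_cluster(
    parent_intensity: float,
    mean_offspring: float,
    sigma: float,
    geometry: PlotGeometry,
    seed_or_rng,
) -> np.ndarray:
    """Thomas cluster pattern.

    Poisson parents at ``parent_intensity`` per m^2; each parent spawns
    Poisson(``mean_offspring``) children displaced by an isotropic Gaussian
    of scale ``sigma`` metres.  Children falling outside the plot are
    discarded, so the realised count is the analytic mean times the edge
    retention fraction.
    """
    if min(parent_intensity, mean_offspring, sigma) <= 0:
        raise ValueError("cluster parameters must be positive")
    rng = _rng(seed_or_rng)
    parents = simulate_poisson(parent_intensity, geometry, rng)
    counts = rng.poisson(mean_offspring, size=len(parents))
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(scale=sigma, size=centers.shape)
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= geometry.width)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= geometry.height)
    )
    return pts[inside]


def simulate_inhibition(
    n: int,
    min_distance: float,
    geometry: PlotGeometry,
    seed_or_rng,
    max_tries: int = 1000,
) -> np.ndarray:
    """Simple sequential inhibition: uniform proposals, rejected within
    ``min_distance`` of an accepted point.  Errors out when the packing is
    infeasible (no placement after ``max_tries`` proposals per point)."""
    if min_distance < 0:
        raise ValueError("min_distance must be non-negative")
    rng = _rng(seed_or_rng)
    pts: list[np.ndarray] = []
    for _ in range(n):
        for _ in range(max_tries):
            p = rng.uniform((0, 0), (geometry.width, geometry.height))
            if not pts or (
                np.min(np.hypot(*(np.array(pts) - p).T)) >= min_distance
            ):
                pts.append(p)
                break
        else:
            raise RuntimeError(
                f"could not place point {len(pts) + 1}/{n} at min_distance="
                f"{min_distance} m; the packing is too dense"
            )
    return np.array(pts).reshape(n, 2)


def jittered_lattice(
    n: int, geometry: PlotGeometry, seed_or_rng, jitter: float = 0.1
) -> np.ndarray:
    """Square lattice filling the plot, each node displaced uniformly by at
    most ``jitter`` times the spacing — a regular pattern with broken ties."""
    rng = _rng(seed_or_rng)
    spacing = np.sqrt(geometry.area_m2 / n)
    xs = np.arange(spacing / 2, geometry.width, spacing)
    ys = np.arange(spacing / 2, geometry.height, spacing)
    grid = np.array([(x, y) for x in xs for y in ys])
    pts = grid + rng.uniform(-jitter * spacing, jitter * spacing, size=grid.shape)
    return np.clip(pts, (0, 0), (geometry.width, geometry.height))


# ---------------------------------------------------------------------------
# diameters
# ---------------------------------------------------------------------------

def assign_dbh(
    n: int,
    stage_mix: Sequence[float] = DEFAULT_STAGE_MIX,
    seed_or_rng=None,
    breaks: Sequence[float] = DEFAULT_STAGE_BREAKS,
) -> np.ndarray:
    """Draw ``n`` DBH values (cm) from a reverse-J stage mixture.

    Each tree's stage is multinomial with probabilities ``stage_mix``; its
    DBH is then a truncated exponential on the stage interval ([b0,b1),
    [b1,b2), [b2, cap]), giving declining abundance in diameter within and
    across stages.
    """
    mix = np.asarray(stage_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1) > 1e-9 or (mix < 0).any():
        raise ValueError("stage_mix must be 3 non-negative proportions summing to 1")
    rng = _rng(seed_or_rng)
    edges = (*breaks, DBH_CAP)
    stages = rng.choice(3, size=n, p=mix)
    u = rng.uniform(size=n)
    dbh = np.empty(n)
    for s in range(3):
        lo, hi = edges[s], edges[s + 1]
        scale = STAGE_DBH_SCALES[s]
        mask = stages == s
        # inverse CDF of an exponential truncated to [lo, hi)
        z = 1.0 - np.exp(-(hi - lo) / scale)
        dbh[mask] = lo - scale * np.log1p(-u[mask] * z)
    return dbh


# ---------------------------------------------------------------------------
# whole communities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesSpec:
    """One species of a synthetic community."""

    label: str
    n_expected: float
    pattern: PatternName = "poisson"
    #: pattern parameters: cluster -> {"n_parents": float, "sigma": float};
    #: inhibition -> {"min_distance": float}; poisson -> none.
    pattern_params: dict = field(default_factory=dict)
    stage_mix: tuple[float, float, float] = DEFAULT_STAGE_MIX


@dataclass(frozen=True)
class AssociationSpec:
    """Intended pairwise quadrat association between two species."""

    species_a: str
    species_b: str
    sign: Literal["+", "-"]
    strength: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.strength <= 1:
            raise ValueError("association strength must be in [0, 1]")
        if self.sign not in ("+", "-"):
            raise ValueError("association sign must be '+' or '-'")


@dataclass(frozen=True)
class CommunitySpec:
    geometry: PlotGeometry
    species: tuple[SpeciesSpec, ...]
    associations: tuple[AssociationSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate species labels")
        seen: set[str] = set()
        for a in self.associations:
            for lab in (a.species_a, a.species_b):
                if lab not in labels:
                    raise ValueError(f"association names unknown species {lab!r}")
                if lab in seen:
                    raise ValueError(
                        f"species {lab!r} appears in more than one association pair"
                    )
                seen.add(lab)


class _PatchRegion:
    """Random habitat patch: half the cells of a coarse grid over the plot.

    Points of positively associated pairs are steered into the same patch,
    negatively associated pairs into patch vs complement, which induces the
    intended co-occurrence signal while keeping positions spatially
    coherent.
    """

    def __init__(self, geometry: PlotGeometry, rng: np.random.Generator):
        self.geometry = geometry
        self.nx = max(int(round(geometry.width / geometry.quadrat_size)), 2)
        self.ny = max(int(round(geometry.height / geometry.quadrat_size)), 2)
        cells = self.nx * self.ny
        chosen = rng.choice(cells, size=cells // 2, replace=False)
        self.cells = set(int(c) for c in chosen)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        cx = np.minimum(
            (pts[:, 0] / self.geometry.width * self.nx).astype(int), self.nx - 1
        )
        cy = np.minimum(
            (pts[:, 1] / self.geometry.height * self.ny).astype(int), self.ny - 1
        )
        flat = cy * self.nx + cx
        member = np.fromiter(
            (int(f) in self.cells for f in flat), dtype=bool, count=len(flat)
        )
        return member


def _steer_points(
    pts: np.ndarray,
    region: _PatchRegion,
    inside: bool,
    strength: float,
    rng: np.random.Generator,
    geometry: PlotGeometry,
) -> np.ndarray:
    """Move each point, with probability ``strength``, to a uniform draw
    from the patch (or its complement) by rejection sampling."""
    out = pts.copy()
    move = rng.uniform(size=len(pts)) < strength
    need = np.flatnonzero(move)
    filled = 0
    while filled < len(need):
        prop = rng.uniform((0, 0), (geometry.width, geometry.height),
                           size=(max(4 * (len(need) - filled), 32), 2))
        ok = region.contains(prop)
        if not inside:
            ok = ~ok
        prop = prop[ok]
        take = min(len(prop), len(need) - filled)
        out[need[filled : filled + take]] = prop[:take]
        filled += take
    return out


def _edge_retention(geometry: PlotGeometry, sigma: float) -> float:
    """Expected fraction of Gaussian(sigma) offspring of a uniform parent
    that stay inside the plot (product of the per-axis retentions)."""

    def axis(L: float) -> float:
        return 1.0 - (2.0 * sigma / (L * np.sqrt(2.0 * np.pi))) * (
            1.0 - np.exp(-(L**2) / (2.0 * sigma**2))
        )

    return axis(geometry.width) * axis(geometry.height)


def _species_points(
    spec: SpeciesSpec, geometry: PlotGeometry, rng: np.random.Generator
) -> np.ndarray:
    area = geometry.area_m2
    if spec.pattern == "poisson":
        return simulate_poisson(spec.n_expected / area, geometry, rng)
    if spec.pattern == "cluster":
        n_parents = spec.pattern_params.get("n_parents", max(spec.n_expected / 15, 3))
        sigma = spec.pattern_params.get("sigma", 5.0)
        # inflate the offspring mean so the expected count survives clipping
        retention = _edge_retention(geometry, sigma)
        return simulate_cluster(
            parent_intensity=n_parents / area,
            mean_offspring=spec.n_expected / n_parents / retention,
            sigma=sigma,
            geometry=geometry,
            seed_or_rng=rng,
        )
    if spec.pattern == "inhibition":
        n = int(round(spec.n_expected))
        return simulate_inhibition(
            n, spec.pattern_params.get("min_distance", 3.0), geometry, rng
        )
    raise ValueError(f"unknown pattern {spec.pattern!r}")


def simulate_community(spec: CommunitySpec) -> tuple[StemMap, dict]:
    """Generate a full marked stand from a community specification.

    Returns the stem map and a truth record: per-species pattern labels and
    per-pair intended association signs, for recovery tests downstream.
    Fully reproducible: the same spec and seed give byte-identical output.
    """
    assoc_of = {}
    patches = {}
    for a in spec.associations:
        patch = _PatchRegion(
            spec.geometry, _label_stream(spec.seed, "assoc", a.species_a, a.species_b)
        )
        patches[(a.species_a, a.species_b)] = patch
        assoc_of[a.species_a] = (a, patch, True)
        # negative pairs: B is steered into the complement of A's patch
        assoc_of[a.species_b] = (a, patch, a.sign == "+")

    frames = []
    for sp in spec.species:
        rng = _label_stream(spec.seed, "species", sp.label)
        pts = _species_points(sp, spec.geometry, rng)
        if sp.label in assoc_of:
            a, patch, inside = assoc_of[sp.label]
            pts = _steer_points(pts, patch, inside, a.strength, rng, spec.geometry)
        dbh = assign_dbh(len(pts), sp.stage_mix, rng)
        frames.append(
            pd.DataFrame(
                {
                    "tree_id": [f"{sp.label}_{i:04d}" for i in range(len(pts))],
                    "species": sp.label,
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "dbh": dbh,
                }
            )
        )
    trees = pd.concat(frames, ignore_index=True)
    stemmap = StemMap(trees=trees, geometry=spec.geometry)
    truth = {
        "seed": spec.seed,
        "species": {
            sp.label: {"pattern": sp.pattern, "n_expected": float(sp.n_expected)}
            for sp in spec.species
        },
        "associations": [
            {
                "species_a": a.species_a,
                "species_b": a.species_b,
                "sign": a.sign,
                "strength": a.strength,
            }
            for a in spec.associations
        ],
    }
    return stemmap, truth


#: Dominant-species densities (trees/ha) of the emulated 0.98 ha stand,
#: in rank order; the tail of minor species brings the stand to ~888/ha.
_DOMINANT_DENSITIES = {
    "QA": 190.82, "AC": 137.76, "UG": 77.55, "CP": 60.20, "SP": 58.16,
    "AG": 57.14, "PA": 56.12, "CK": 47.96, "MH": 32.65, "TV": 22.45,
    "QL": 18.37,
}
_MINOR_DENSITIES = {
    f"M{i:02d}": d
    for i, d in enumerate(
        [14.0, 13.0, 12.0, 11.0, 11.0, 10.0, 10.0, 10.0, 10.0, 9.0, 9.0, 9.5]
    )
}
_CLUSTERED = {"AC": 8.0, "CP": 6.0, "SP": 5.0, "CK": 5.0, "QL": 7.0}


def default_community_spec(seed: int = 0) -> CommunitySpec:
    """Emulated study stand: 140 x 70 m, ~870 stems, 11 dominant species.

    Dominant densities follow the observed ranking (a tail of minor species
    brings the stand to ~888 trees/ha); juvenile-heavy species are
    clustered, the rest random.  Two association pairs give the analysis
    known structure to detect: CK-MH positive, SP-TV negative (each species
    may join at most one pair).
    """
    geometry = PlotGeometry(width=140.0, height=70.0, quadrat_size=14.0, buffer_width=5.0)
    species = []
    for label, dens in {**_DOMINANT_DENSITIES, **_MINOR_DENSITIES}.items():
        n_exp = dens * geometry.area_ha
        if label in _CLUSTERED:
            species.append(
                SpeciesSpec(
                    label=label,
                    n_expected=n_exp,
                    pattern="cluster",
                    pattern_params={"sigma": _CLUSTERED[label]},
                    stage_mix=(0.6, 0.3, 0.1),
                )
            )
        else:
            species.append(SpeciesSpec(label=label, n_expected=n_exp))
    associations = (
        AssociationSpec("CK", "MH", "+", 0.6),
        AssociationSpec("SP", "TV", "-", 0.5),
    )
    return CommunitySpec(
        geometry=geometry,
        species=tuple(species),
        associations=associations,
        seed=seed,
    )
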