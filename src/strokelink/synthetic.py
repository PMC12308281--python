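"""Synthetic stroke-cohort generator.

Emulates the statistical structure the analysis assumes without any patient
data: a unilateral lesion disrupts streamlines of a synthetic tractography
atlas (structural disconnection, SDC); the resulting lesion severity drives
a single latent deficit dimension t; and t expresses jointly in

* functional-connectivity edges, with the field's hallmark stroke pattern
  planted in the X-salience (interhemispheric edges between sensory-like
  networks weighted negatively, intrahemispheric edges involving
  higher-order networks positively), and
* multi-domain behavioural scores.

Block gains are calibrated so the population correlation between the two
planted composite scores equals ``latent_effect``: each block's composite
correlates sqrt(latent_effect) with the shared latent, so their product is
the target.  Ground truth (latent scores, planted saliences, severities) is
returned for recovery tests.  Everything is deterministic given the seed;
sub-streams are derived from fixed offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    LesionMask,
    ParcelScheme,
    StreamlineAtlas,
    edge_index,
    edge_labels,
    streamline_disruption,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticCohort",
    "make_parcel_scheme",
    "make_streamline_atlas",
    "sample_lesions",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

# fixed sub-seed offsets: one explicit stream per random ingredient
_ATLAS_OFFSET = 1
_LESION_OFFSET = 2
_NOISE_OFFSET = 3
_MISSING_OFFSET = 4

_DOMAIN_NAMES = ["language", "attention", "verbal_memory", "spatial_memory", "motor"]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the target cohort at desk scale: 81 participants, 41
    behavioural scores in 5 domains, 13 functional networks per hemisphere
    with one parcel each (the generator is parcellation-size-agnostic), a
    planted composite correlation of 0.7 and unit measurement noise in both
    blocks.
    """

    n_participants: int = 81
    n_parcels_per_hemisphere: int = 13
    n_networks_per_hemisphere: int = 13
    n_behaviour_measures: int = 41
    n_domains: int = 5
    grid_dims: tuple = (24, 12, 12)
    lesion_radius_range: tuple = (2.0, 4.0)
    streamlines_per_pair: int = 5
    wobble: float = 0.5
    cortex_fraction: float = 0.5
    route_depth: bool = True
    latent_effect: float = 0.7
    noise_sd_x: float = 1.0
    noise_sd_y: float = 1.0
    latent_noise_sd: float = 0.5
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_participants, self.n_parcels_per_hemisphere,
                  self.n_networks_per_hemisphere, self.n_behaviour_measures,
                  self.n_domains, self.streamlines_per_pair]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.latent_effect < 1:
            raise ValueError("latent_effect must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.grid_dims) != 3 or any(g < 2 for g in self.grid_dims):
            raise ValueError("grid_dims must be three voxel counts >= 2")
        if self.grid_dims[0] % 2 != 0:
            raise ValueError("first grid axis must split into two hemispheres")
        if self.n_parcels_per_hemisphere % self.n_networks_per_hemisphere != 0:
            raise ValueError("parcels per hemisphere must divide evenly into networks")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid lesion radius range")
        if self.latent_effect == 0 and (self.noise_sd_x == 0 or self.noise_sd_y == 0):
            raise ValueError("latent_effect=0 with zero noise is degenerate")
        if self.n_domains > self.n_behaviour_measures:
            raise ValueError("more domains than behaviour measures")


@dataclass
class GroundTruth:
    """Generative analogue of the first latent component."""

    latent_scores: np.ndarray        # (n,) standardized latent severity t
    planted_x_salience: np.ndarray   # unit vector over FC edges
    planted_y_salience: np.ndarray   # unit vector over behaviour measures
    lesion_severity: np.ndarray      # (n,) fraction of atlas streamlines disrupted


@dataclass
class SyntheticCohort:
    scheme: ParcelScheme
    atlas: StreamlineAtlas
    lesions: list                    # list of LesionMask
    fc_edges: np.ndarray             # (n, E) Fisher-z-scale edge matrix
    behaviour: pd.DataFrame          # (n, m) with domain-annotated columns
    truth: GroundTruth
    config: SyntheticConfig
    time_series: np.ndarray | None = None

    @property
    def n_participants(self) -> int:
        return self.fc_edges.shape[0]

    @property
    def edge_names(self) -> list:
        return edge_labels(self.scheme)


# ---------------------------------------------------------------------------
# parcel scheme
# ---------------------------------------------------------------------------


def _cell_grid(hemi_dims: np.ndarray, n_parcels: int) -> tuple:
    """Smallest per-axis cell counts whose product covers n_parcels.

    Grows the axis that currently has the largest cells, so blocks stay
    roughly cubic; raises if the grid cannot host one voxel per parcel cell.
    """
    counts = np.ones(3, dtype=int)
    while counts.prod() < n_parcels:
        sizes = hemi_dims / counts
        axis = int(np.argmax(sizes))
        if counts[axis] + 1 > hemi_dims[axis]:
            candidates = [a for a in range(3) if counts[a] + 1 <= hemi_dims[a]]
            if not candidates:
                raise ValueError(
                    f"grid {tuple(hemi_dims)} per hemisphere too small for "
                    f"{n_parcels} parcels")
            axis = max(candidates, key=lambda a: hemi_dims[a] / counts[a])
        counts[axis] += 1
    return tuple(counts)


def make_parcel_scheme(n_per_hemi: int, n_networks: int, grid_dims: tuple,
                       cortex_fraction: float = 0.5) -> ParcelScheme:
    """Tile each hemisphere with one voxel block per parcel, mirror-symmetric.

    The first grid axis is split into a left half (low x) and a right half;
    right-hemisphere parcels are exact mirror images of left ones.  Networks
    are assigned in contiguous, balanced groups within each hemisphere.

    Parcels (grey matter) occupy only the top ``cortex_fraction`` of the
    third axis; the space below is white matter, left free for streamlines
    to course through — the anatomy that lets a small deep lesion disconnect
    much while damaging little grey matter.  ``cortex_fraction=1`` tiles the
    whole hemisphere.
    """
    if n_per_hemi % n_networks != 0:
        raise ValueError("n_per_hemi must divide evenly into n_networks groups")
    if not 0 < cortex_fraction <= 1:
        raise ValueError("cortex_fraction must be in (0, 1]")
    gx, gy, gz = grid_dims
    if gx % 2 != 0:
        raise ValueError("first grid axis must be even to split hemispheres")
    z_cortex = int(np.ceil(gz * cortex_fraction))
    z0_cortex = gz - z_cortex
    hemi_dims = np.array([gx // 2, gy, z_cortex])
    cells = _cell_grid(hemi_dims, n_per_hemi)
    block = hemi_dims // np.array(cells)
    if (block < 1).any():
        raise ValueError("grid too small for the requested parcel count")

    per_net = n_per_hemi // n_networks
    cell_coords = [(cx, cy, cz)
                   for cx in range(cells[0])
                   for cy in range(cells[1])
                   for cz in range(cells[2])][:n_per_hemi]

    members: list = []
    hemis: list = []
    nets: list = []
    for hemi in ("L", "R"):
        for k, (cx, cy, cz) in enumerate(cell_coords):
            x0, y0, z0 = np.array([cx, cy, cz]) * block
            z0 += z0_cortex
            xs = np.arange(x0, x0 + block[0])
            ys = np.arange(y0, y0 + block[1])
            zs = np.arange(z0, z0 + block[2])
            vx, vy, vz = np.meshgrid(xs, ys, zs, indexing="ij")
            vox = np.column_stack([vx.ravel(), vy.ravel(), vz.ravel()])
            if hemi == "R":
                vox = vox.copy()
                vox[:, 0] = gx - 1 - vox[:, 0]
            members.append(vox)
            hemis.append(hemi)
            nets.append(f"net{str(k // per_net + 1).zfill(2)}")
    centroids = np.array([v.mean(axis=0) for v in members])
    scheme = ParcelScheme(
        hemisphere=np.array(hemis),
        network=np.array(nets),
        voxel_members=members,
        centroids=centroids,
        grid_dims=tuple(grid_dims),
    )
    scheme.validate()
    return scheme


# ---------------------------------------------------------------------------
# streamline atlas
# ---------------------------------------------------------------------------


def _densify(points: np.ndarray) -> np.ndarray:
    """Subdivide segments so consecutive vertices are <= 1 voxel apart."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        dist = float(np.linalg.norm(b - a))
        n_seg = max(1, int(np.ceil(dist / 1.0)))
        for s in range(1, n_seg + 1):
            out.append(a + (b - a) * (s / n_seg))
    return np.asarray(out)


def make_streamline_atlas(scheme: ParcelScheme, streamlines_per_pair: int = 5,
                          wobble: float = 0.0, seed: int = 0,
                          route_depth: bool = False) -> StreamlineAtlas:
    """Polyline streamlines between every unordered parcel pair.

    With ``wobble=0`` (and no depth routing) each streamline is the straight
    centroid-to-centroid segment; otherwise endpoints are random member
    voxels and interior vertices get Gaussian jitter (sd ``wobble`` voxels,
    tapered to zero at the endpoints), then re-densified to keep vertex
    spacing <= 1 voxel.

    ``route_depth=True`` makes each streamline dive below the parcel layer
    through two white-matter waypoints before reaching the other endpoint,
    the way association/commissural tracts course beneath the cortex.  It
    requires a scheme whose parcels leave deep space free (see
    ``make_parcel_scheme``'s ``cortex_fraction``).
    """
    if streamlines_per_pair < 1:
        raise ValueError("streamlines_per_pair must be >= 1")
    if scheme.n_parcels == 0:
        raise ValueError("empty parcel scheme")
    rng = np.random.default_rng(seed)
    lines: list = []
    pairs: list = []
    p = scheme.n_parcels
    z_floor = min(v[:, 2].min() for v in scheme.voxel_members)
    if route_depth and z_floor < 2:
        raise ValueError("route_depth needs free white-matter space below the parcels")
    for i in range(p):
        for j in range(i + 1, p):
            for _ in range(streamlines_per_pair):
                if wobble == 0:
                    e1 = scheme.centroids[i]
                    e2 = scheme.centroids[j]
                else:
                    vi = scheme.voxel_members[i]
                    vj = scheme.voxel_members[j]
                    e1 = vi[rng.integers(0, len(vi))].astype(float)
                    e2 = vj[rng.integers(0, len(vj))].astype(float)
                if route_depth:
                    zd = rng.uniform(0.5, z_floor - 0.5)
                    w1 = np.array([e1[0], e1[1], zd])
                    w2 = np.array([e2[0], e2[1], zd])
                    waypoints = np.vstack([e1, w1, w2, e2])
                else:
                    waypoints = np.vstack([e1, e2])
                base = _densify(waypoints)
                if wobble > 0 and len(base) > 2:
                    tpar = np.linspace(0.0, 1.0, len(base))
                    taper = np.sin(np.pi * tpar)[:, None]
                    base = base + taper * rng.normal(0.0, wobble, size=base.shape)
                    base = _densify(base)
                    dims = np.asarray(scheme.grid_dims, dtype=float)
                    base = np.clip(base, 0.0, dims - 1.0)
                lines.append(base)
                pairs.append((i + 1, j + 1))
    atlas = StreamlineAtlas(streamlines=lines, endpoints=np.asarray(pairs, dtype=int))
    atlas.validate(scheme)
    return atlas


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------


def sample_lesions(scheme: ParcelScheme, config: SyntheticConfig, seed: int,
                   atlas: StreamlineAtlas | None = None) -> tuple[list, np.ndarray]:
    """One roughly spherical unilateral lesion per participant.

    Lesion severity is the fraction of atlas streamlines the lesion
    intersects (0 when no atlas is given or nothing is hit) — monotone in
    the number of disrupted streamlines by construction.
    """
    gx, gy, gz = scheme.grid_dims
    hx = gx // 2
    lo, hi = config.lesion_radius_range
    if 2 * hi + 1 > min(hx, gy, gz):
        raise ValueError("lesion radius range exceeds hemisphere extent")
    rng = np.random.default_rng(seed)
    xs, ys, zs = np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz), indexing="ij")
    masks: list = []
    severities = np.zeros(config.n_participants)
    for i in range(config.n_participants):
        radius = rng.uniform(lo, hi)
        hemi = rng.integers(0, 2)  # 0 = left, 1 = right
        cx = rng.uniform(radius, hx - 1 - radius)
        if hemi == 1:
            cx = gx - 1 - cx
        cy = rng.uniform(radius, gy - 1 - radius)
        cz = rng.uniform(radius, gz - 1 - radius)
        ball = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= radius ** 2
        if not ball.any():
            ball[int(round(cx)), int(round(cy)), int(round(cz))] = True
        mask = LesionMask(grid=ball)
        masks.append(mask)
        if atlas is not None:
            hit = streamline_disruption(mask, atlas)
            severities[i] = hit.mean()
    return masks, severities


# ---------------------------------------------------------------------------
# planted saliences
# ---------------------------------------------------------------------------


def _planted_x_salience(scheme: ParcelScheme) -> np.ndarray:
    """Unit FC-edge salience with the stroke-like sign structure.

    Negative weight on interhemispheric edges whose two parcels both belong
    to sensory-like networks (the first half of the network list); positive
    weight on intrahemispheric edges involving at least one higher-order
    network (the remaining networks); zero elsewhere.
    """
    nets = list(dict.fromkeys(scheme.network))
    n_sensory = int(np.ceil(len(nets) / 2))
    sensory = set(nets[:n_sensory])
    net_arr = scheme.network
    hemi = scheme.hemisphere
    ii, jj = edge_index(scheme.n_parcels)
    inter = hemi[ii] != hemi[jj]
    both_sensory = np.isin(net_arr[ii], list(sensory)) & np.isin(net_arr[jj], list(sensory))
    any_higher = ~np.isin(net_arr[ii], list(sensory)) | ~np.isin(net_arr[jj], list(sensory))
    u = np.zeros(len(ii))
    u[inter & both_sensory] = -1.0
    u[(~inter) & any_higher] = 1.0
    norm = np.linalg.norm(u)
    if norm == 0:  # degenerate tiny schemes: fall back to a uniform vector
        u[:] = 1.0
        norm = np.linalg.norm(u)
    return u / norm


def domain_assignment(n_measures: int, n_domains: int) -> list:
    """Contiguous near-equal domain blocks (41 measures -> 9/8/8/8/8)."""
    bounds = np.linspace(0, n_measures, n_domains + 1).round().astype(int)
    names = (_DOMAIN_NAMES * ((n_domains // len(_DOMAIN_NAMES)) + 1))[:n_domains]
    out = []
    for d in range(n_domains):
        out.extend([names[d]] * (bounds[d + 1] - bounds[d]))
    return out


def _planted_y_salience(n_measures: int, n_domains: int) -> np.ndarray:
    """Unit behaviour salience: smooth positive profile with one contrarian.

    Magnitudes vary smoothly across measures; one attention-like measure is
    sign-flipped, echoing the occasional deficit score that loads opposite
    to its domain.
    """
    j = np.arange(n_measures)
    # magnitudes sweep from strong to near zero across each domain's measures,
    # so the salience has genuine variance around its mean (as real deficit
    # profiles do), not a near-constant positive weight
    v = 0.35 + np.sin(2 * np.pi * (j + 0.7) / max(n_measures / max(n_domains, 1), 2))
    if n_measures >= 3:
        v[1] = -abs(v[1]) - 0.3
    return v / np.linalg.norm(v)


def _edge_baseline(scheme: ParcelScheme) -> np.ndarray:
    """Fisher-z-like baseline: stronger intra- than interhemispheric edges."""
    ii, jj = edge_index(scheme.n_parcels)
    intra = scheme.hemisphere[ii] == scheme.hemisphere[jj]
    return np.where(intra, 0.25, 0.10)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _gain(sigma: float, rho: float) -> float:
    """Block gain making the block composite correlate sqrt(rho) with t.

    With X u = g t + sigma eps (unit-norm u, iid noise), corr(X u, t) =
    g / sqrt(g^2 + sigma^2); solving for corr = sqrt(rho) gives
    g = sigma sqrt(rho / (1 - rho)), and the product over the two blocks
    makes corr(X u, Y v) = rho.
    """
    if rho == 0:
        return 0.0
    return float(sigma * np.sqrt(rho / (1.0 - rho)))


def measure_names(config: SyntheticConfig) -> list:
    domains = domain_assignment(config.n_behaviour_measures, config.n_domains)
    return [f"{d}__m{str(i + 1).zfill(2)}" for i, d in enumerate(domains)]


def generate_cohort(config: SyntheticConfig, truth: GroundTruth | None = None,
                    participant_seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (deterministic given seeds).

    Passing an existing ``truth`` keeps the planted saliences (and the
    scheme/atlas, which depend only on the config) while drawing a fresh
    participant sample — the replication-cohort construction.  A separate
    ``participant_seed`` draws new lesions/noise under the same truth.
    """
    config.validate()
    scheme = make_parcel_scheme(config.n_parcels_per_hemisphere,
                                config.n_networks_per_hemisphere,
                                config.grid_dims,
                                cortex_fraction=config.cortex_fraction)
    atlas = make_streamline_atlas(scheme, config.streamlines_per_pair,
                                  wobble=config.wobble,
                                  seed=config.seed + _ATLAS_OFFSET,
                                  route_depth=config.route_depth)
    pseed = config.seed if participant_seed is None else participant_seed
    lesions, severity = sample_lesions(scheme, config, seed=pseed + _LESION_OFFSET,
                                       atlas=atlas)

    sd_sev = severity.std()
    if sd_sev == 0:
        raise ValueError("degenerate lesion sample: all severities identical")
    rng_noise = np.random.default_rng(pseed + _NOISE_OFFSET)
    t = (severity - severity.mean()) / sd_sev
    if config.latent_noise_sd > 0:
        t = t + rng_noise.normal(0.0, config.latent_noise_sd, size=len(t))
    t = (t - t.mean()) / t.std()

    if truth is None:
        u = _planted_x_salience(scheme)
        v = _planted_y_salience(config.n_behaviour_measures, config.n_domains)
    else:
        u = truth.planted_x_salience
        v = truth.planted_y_salience

    n = config.n_participants
    e = scheme.n_edges
    m = config.n_behaviour_measures
    gx = _gain(config.noise_sd_x, config.latent_effect)
    gy = _gain(config.noise_sd_y, config.latent_effect)
    fc = (_edge_baseline(scheme)[None, :]
          + gx * np.outer(t, u)
          + config.noise_sd_x * rng_noise.standard_normal((n, e)))
    beh = (10.0
           + gy * np.outer(t, v)
           + config.noise_sd_y * rng_noise.standard_normal((n, m)))

    names = measure_names(config)
    behaviour = pd.DataFrame(beh, columns=names)
    if config.missing_rate > 0:
        rng_miss = np.random.default_rng(pseed + _MISSING_OFFSET)
        mask = rng_miss.random((n, m)) < config.missing_rate
        for col in range(m):  # keep every measure observable at least once
            if mask[:, col].all():
                mask[rng_miss.integers(0, n), col] = False
        behaviour = behaviour.mask(mask)

    new_truth = GroundTruth(latent_scores=t, planted_x_salience=u,
                            planted_y_salience=v, lesion_severity=severity)
    return SyntheticCohort(scheme=scheme, atlas=atlas, lesions=lesions,
                           fc_edges=fc, behaviour=behaviour, truth=new_truth,
                           config=config)


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, out_dir, write_volumes: bool = True) -> Path:
    """Write a cohort directory (TSV/JSON; lesion masks as NIfTI volumes)."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = [f"sub{str(i + 1).zfill(3)}" for i in range(cohort.n_participants)]

    beh = cohort.behaviour.copy()
    beh.insert(0, "participant_id", pid)
    beh.to_csv(out / "behaviour.tsv", sep="\t", index=False)

    fc = pd.DataFrame(cohort.fc_edges, columns=cohort.edge_names)
    fc.insert(0, "participant_id", pid)
    fc.to_csv(out / "fc_edges.tsv", sep="\t", index=False)

    cohort.scheme.to_frame().to_csv(out / "scheme.tsv", sep="\t", index=False)
    with open(out / "scheme_voxels.json", "w") as fh:
        json.dump([v.tolist() for v in cohort.scheme.voxel_members], fh)
    with open(out / "grid.json", "w") as fh:
        json.dump({"grid_dims": list(cohort.scheme.grid_dims)}, fh)

    with open(out / "atlas.json", "w") as fh:
        json.dump({
            "streamlines": [s.tolist() for s in cohort.atlas.streamlines],
            "endpoints": cohort.atlas.endpoints.tolist(),
        }, fh)

    with open(out / "truth.json", "w") as fh:
        json.dump({
            "latent_scores": cohort.truth.latent_scores.tolist(),
            "planted_x_salience": cohort.truth.planted_x_salience.tolist(),
            "planted_y_salience": cohort.truth.planted_y_salience.tolist(),
            "lesion_severity": cohort.truth.lesion_severity.tolist(),
        }, fh)

    cfg = asdict(cohort.config)
    cfg["grid_dims"] = list(cfg["grid_dims"])
    cfg["lesion_radius_range"] = list(cfg["lesion_radius_range"])
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=1)

    if write_volumes:
        les_dir = out / "lesions"
        les_dir.mkdir(exist_ok=True)
        for name, mask in zip(pid, cohort.lesions):
            img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine=np.eye(4))
            nib.save(img, les_dir / f"{name}_lesion.nii.gz")
    return out


def read_cohort(cohort_dir) -> SyntheticCohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    import nibabel as nib

    d = Path(cohort_dir)
    for required in ("behaviour.tsv", "fc_edges.tsv", "scheme.tsv",
                     "atlas.json", "truth.json", "config.json"):
        if not (d / required).exists():
            raise FileNotFoundError(f"cohort directory is missing {required}")
    with open(d / "config.json") as fh:
        cfg = json.load(fh)
    cfg["grid_dims"] = tuple(cfg["grid_dims"])
    cfg["lesion_radius_range"] = tuple(cfg["lesion_radius_range"])
    config = SyntheticConfig(**cfg)

    frame = pd.read_csv(d / "scheme.tsv", sep="\t")
    with open(d / "scheme_voxels.json") as fh:
        members = [np.asarray(v, dtype=int) for v in json.load(fh)]
    with open(d / "grid.json") as fh:
        grid_dims = tuple(json.load(fh)["grid_dims"])
    scheme = ParcelScheme(
        hemisphere=frame["hemisphere"].to_numpy(),
        network=frame["network"].to_numpy(),
        voxel_members=members,
        centroids=frame[["centroid_x", "centroid_y", "centroid_z"]].to_numpy(),
        grid_dims=grid_dims,
    )
    with open(d / "atlas.json") as fh:
        a = json.load(fh)
    atlas = StreamlineAtlas(
        streamlines=[np.asarray(s, dtype=float) for s in a["streamlines"]],
        endpoints=np.asarray(a["endpoints"], dtype=int),
    )
    beh = pd.read_csv(d / "behaviour.tsv", sep="\t")
    pid = beh.pop("participant_id")
    fc = pd.read_csv(d / "fc_edges.tsv", sep="\t")
    fc = fc.drop(columns=["participant_id"])
    with open(d / "truth.json") as fh:
        t = json.load(fh)
    truth = GroundTruth(
        latent_scores=np.asarray(t["latent_scores"], dtype=float),
        planted_x_salience=np.asarray(t["planted_x_salience"], dtype=float),
        planted_y_salience=np.asarray(t["planted_y_salience"], dtype=float),
        lesion_severity=np.asarray(t["lesion_severity"], dtype=float),
    )
    lesions = []
    les_dir = d / "lesions"
    if les_dir.exists():
        for name in pid:
            img = nib.load(les_dir / f"{name}_lesion.nii.gz")
            lesions.append(LesionMask(grid=np.asarray(img.dataobj) > 0))
    return SyntheticCohort(scheme=scheme, atlas=atlas, lesions=lesions,
                           fc_edges=fc.to_numpy(), behaviour=beh, truth=truth,
                           config=config)
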