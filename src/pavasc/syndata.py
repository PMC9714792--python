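"""Synthetic single-cell datasets and vessel images with known ground truth.

Two generators:

* :func:`simulate_counts` draws negative-binomial UMI counts for a
  multi-population, two-condition pulmonary-artery-like design with planted
  population markers, condition fold changes, mitochondrial read fractions
  and active ligand-receptor channels.
* :func:`simulate_vessel_image` renders a transverse vessel cross section as
  a multichannel raster: nuclei, an endothelial (VWF) ring at the lumen
  boundary, a neointimal/synthetic-SMC (VCAN) band, a medial smooth-muscle
  (ACTA2) annulus, an adventitial (DCN) annulus and a proliferation-marker
  channel lit inside a planted subset of medial nuclei.

Both return a :class:`SynthTruth` recording every planted parameter so that
downstream statistics can be tested for recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData

CONDITIONS = ("donor", "PAH")

__all__ = [
    "SimExprParams",
    "SimImageParams",
    "SynthTruth",
    "simulate_counts",
    "simulate_vessel_image",
    "NucleusPlacementError",
]


class NucleusPlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement exhausts its retry cap."""


def _default_lr_channels() -> list[tuple[str, str, str, str]]:
    # (source population, target population, ligand gene, receptor gene);
    # includes one autocrine channel.
    return [
        ("pop00", "pop01", "LIGA", "RECA"),
        ("pop02", "pop03", "LIGB", "RECB"),
        ("pop01", "pop01", "LIGC", "RECC"),
    ]


@dataclass
class SimExprParams:
    """Parameters of the expression simulator.

    Defaults emulate the design of the source study: 14 cell populations
    observed in 2 conditions x 3 samples, ~4,800 captured cells per sample,
    and per-cell depth/complexity in the range of droplet scRNA-Seq of
    dissociated pulmonary arteries (median ~1,000 detected genes and
    ~2,800 UMIs per cell at the chosen baseline mean and gene count).
    """

    n_populations: int = 14
    n_samples_per_condition: int = 3
    cells_per_sample: int = 4800
    n_genes: int = 2000
    baseline_mean: float = 1.4
    dispersion: float = 2.0
    poisson: bool = False
    marker_genes_per_population: int = 20
    marker_log2fc: float = 2.0
    condition_de_genes: int = 50
    condition_log2fc: float = 1.0
    n_mito_genes: int = 13
    mito_fraction_range: tuple[float, float] = (0.01, 0.04)
    proportions_by_condition: Mapping[str, Sequence[float]] | None = None
    active_lr_channels: list[tuple[str, str, str, str]] = field(
        default_factory=_default_lr_channels
    )
    lr_log2fc: float = 1.5
    seed: int = 0

    def population_names(self) -> list[str]:
        return [f"pop{i:02d}" for i in range(self.n_populations)]

    def validate(self) -> None:
        if self.n_populations < 1 or self.n_samples_per_condition < 1:
            raise ValueError("population and sample counts must be positive")
        if self.cells_per_sample < 1 or self.n_genes < 1:
            raise ValueError("cells_per_sample and n_genes must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if not self.poisson and not self.dispersion > 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        pops = set(self.population_names())
        lr_genes: list[str] = []
        for src, tgt, lig, rec in self.active_lr_channels:
            if src not in pops or tgt not in pops:
                raise ValueError(
                    f"LR channel references unknown population: {src!r}/{tgt!r}"
                )
            for g in (lig, rec):
                if g not in lr_genes:
                    lr_genes.append(g)
        demand = (
            self.n_mito_genes
            + self.n_populations * self.marker_genes_per_population
            + self.condition_de_genes
            + len(lr_genes)
        )
        if demand > self.n_genes:
            raise ValueError(
                f"planted structure needs {demand} genes but n_genes={self.n_genes}"
            )
        if self.proportions_by_condition is not None:
            for cond in CONDITIONS:
                if cond not in self.proportions_by_condition:
                    raise ValueError(f"missing proportions for condition {cond!r}")
                p = np.asarray(self.proportions_by_condition[cond], dtype=float)
                if p.shape != (self.n_populations,):
                    raise ValueError("proportion vector length != n_populations")
                if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                    raise ValueError(f"proportions for {cond!r} must sum to 1")


@dataclass
class SimImageParams:
    """Parameters of the vessel-image simulator.

    Radii (in pixels, strictly increasing) delimit the concentric layers of
    a transverse section: open lumen, neointimal band, media, adventitia.
    ``channel_snr`` is signal amplitude over Gaussian noise sigma;
    ``numpy.inf`` gives a noise-free image.
    """

    image_size: int = 256
    lumen_radius: float = 40.0
    media_inner_radius: float = 55.0
    media_outer_radius: float = 85.0
    adventitia_outer_radius: float = 110.0
    n_medial_nuclei: int = 40
    n_outer_nuclei: int = 10
    nucleus_radius: float = 4.0
    positive_nucleus_fraction: float = 0.25
    channel_snr: float = 20.0
    vwf_thickness: float = 3.0
    placement_retries: int = 1000
    seed: int = 0

    def validate(self) -> None:
        radii = (
            self.lumen_radius,
            self.media_inner_radius,
            self.media_outer_radius,
            self.adventitia_outer_radius,
        )
        if not all(r2 > r1 for r1, r2 in zip(radii, radii[1:])):
            raise ValueError("layer radii must be strictly increasing")
        if radii[0] <= 0:
            raise ValueError("lumen_radius must be positive")
        if not 0 <= self.positive_nucleus_fraction <= 1:
            raise ValueError("positive_nucleus_fraction must be in [0, 1]")
        if self.channel_snr <= 0:
            raise ValueError("channel_snr must be positive")
        if self.adventitia_outer_radius >= self.image_size / 2:
            raise ValueError("outer radius does not fit inside the image")


@dataclass
class SynthTruth:
    """All planted parameters of a simulation run, for recovery testing."""

    params: dict
    marker_genes: dict = field(default_factory=dict)
    condition_de_genes: list = field(default_factory=list)
    mito_genes: list = field(default_factory=list)
    lr_channels: list = field(default_factory=list)
    proportions: dict = field(default_factory=dict)
    cell_ids: list = field(default_factory=list)
    cell_population: list = field(default_factory=list)
    cell_condition: list = field(default_factory=list)
    cell_sample: list = field(default_factory=list)
    nuclei: list = field(default_factory=list)
    ring_radii: dict = field(default_factory=dict)
    channel_roles: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _jsonable(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# expression simulator
# ---------------------------------------------------------------------------


def simulate_counts(params: SimExprParams) -> tuple[AnnData, SynthTruth]:
    """Draw a counts matrix with planted structure.

    Returns an :class:`~anndata.AnnData` (cells x genes, integer counts in
    ``X``, per-cell ``sample``/``condition``/``population`` in ``obs``, a
    boolean ``mt`` flag in ``var``) and the matching :class:`SynthTruth`.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    pops = params.population_names()
    n_pop = params.n_populations

    # --- gene bookkeeping: disjoint blocks of the gene index space
    gene_names = [f"G{i:04d}" for i in range(params.n_genes)]
    cursor = 0
    mito_idx = np.arange(cursor, cursor + params.n_mito_genes)
    cursor += params.n_mito_genes
    for i in mito_idx:
        gene_names[i] = "MT-" + gene_names[i]
    marker_idx = {}
    for p in pops:
        marker_idx[p] = np.arange(cursor, cursor + params.marker_genes_per_population)
        cursor += params.marker_genes_per_population
    cond_idx = np.arange(cursor, cursor + params.condition_de_genes)
    cursor += params.condition_de_genes
    lr_gene_index: dict[str, int] = {}
    for src, tgt, lig, rec in params.active_lr_channels:
        for g in (lig, rec):
            if g not in lr_gene_index:
                lr_gene_index[g] = cursor
                gene_names[cursor] = g
                cursor += 1

    # --- proportions
    if params.proportions_by_condition is None:
        props = {c: np.full(n_pop, 1.0 / n_pop) for c in CONDITIONS}
    else:
        props = {
            c: np.asarray(params.proportions_by_condition[c], dtype=float)
            for c in CONDITIONS
        }

    # --- per-sample generation
    blocks, obs_rows = [], []
    pop_of = {p: i for i, p in enumerate(pops)}
    for cond in CONDITIONS:
        for s in range(params.n_samples_per_condition):
            sample = f"{cond}_{s + 1}"
            labels = rng.choice(n_pop, size=params.cells_per_sample, p=props[cond])
            mu = np.full(
                (params.cells_per_sample, params.n_genes),
                params.baseline_mean,
                dtype=np.float64,
            )
            for p in pops:
                rows = labels == pop_of[p]
                if rows.any():
                    mu[np.ix_(rows, marker_idx[p])] *= 2.0 ** params.marker_log2fc
            if cond == "PAH" and len(cond_idx):
                mu[:, cond_idx] *= 2.0 ** params.condition_log2fc
            for src, tgt, lig, rec in params.active_lr_channels:
                rows = labels == pop_of[src]
                mu[rows, lr_gene_index[lig]] *= 2.0 ** params.lr_log2fc
                rows = labels == pop_of[tgt]
                mu[rows, lr_gene_index[rec]] *= 2.0 ** params.lr_log2fc
            # plant per-cell mitochondrial fractions by rescaling the MT block
            if len(mito_idx):
                frac = rng.uniform(*params.mito_fraction_range, size=params.cells_per_sample)
                non_mito = np.delete(np.arange(params.n_genes), mito_idx)
                non_total = mu[:, non_mito].sum(axis=1)
                per_gene = frac / (1.0 - frac) * non_total / len(mito_idx)
                mu[:, mito_idx] = per_gene[:, None]
            counts = _sample_counts(rng, mu, params)
            blocks.append(counts)
            for i, lab in enumerate(labels):
                obs_rows.append((f"{sample}_CELL{i:05d}", sample, cond, pops[lab]))

    X = np.vstack(blocks)
    obs = pd.DataFrame(
        obs_rows, columns=["cell_id", "sample", "condition", "population"]
    ).set_index("cell_id")
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    var["mt"] = [g.startswith("MT-") for g in gene_names]
    adata = AnnData(X=X, obs=obs, var=var)

    truth = SynthTruth(
        params=dataclasses.asdict(params),
        marker_genes={p: [gene_names[i] for i in marker_idx[p]] for p in pops},
        condition_de_genes=[gene_names[i] for i in cond_idx],
        mito_genes=[gene_names[i] for i in mito_idx],
        lr_channels=[
            {"source": s, "target": t, "ligand": l, "receptor": r}
            for s, t, l, r in params.active_lr_channels
        ],
        proportions={c: props[c].tolist() for c in CONDITIONS},
        cell_ids=list(adata.obs_names),
        cell_population=list(adata.obs["population"]),
        cell_condition=list(adata.obs["condition"]),
        cell_sample=list(adata.obs["sample"]),
    )
    return adata, truth


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, params: SimExprParams):
    """NB(mean mu, dispersion theta): variance = mu + mu^2/theta."""
    if params.poisson or np.isinf(params.dispersion):
        return rng.poisson(mu).astype(np.int32)
    theta = params.dispersion
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p).astype(np.int32)


# ---------------------------------------------------------------------------
# vessel-image simulator
# ---------------------------------------------------------------------------

CHANNEL_ROLES = ("dapi", "vwf", "vcan", "acta2", "dcn", "marker")
#: channels combined to assess the overall vessel shape (neointima + media)
SHAPE_CHANNELS = ("vcan", "acta2")


def simulate_vessel_image(params: SimImageParams) -> tuple[np.ndarray, SynthTruth]:
    """Render a (channels, rows, cols) float32 vessel section.

    Channel order follows :data:`CHANNEL_ROLES`.  The truth records every
    nucleus center, its medial status (center inside the media annulus) and
    planted marker positivity.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.image_size
    c0 = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n]
    r = np.hypot(rows - c0, cols - c0)

    img = np.zeros((len(CHANNEL_ROLES), n, n), dtype=np.float32)
    ch = {role: i for i, role in enumerate(CHANNEL_ROLES)}
    img[ch["vwf"]][(r >= params.lumen_radius) & (r < params.lumen_radius + params.vwf_thickness)] = 1.0
    img[ch["vcan"]][(r >= params.lumen_radius) & (r < params.media_inner_radius)] = 1.0
    img[ch["acta2"]][(r >= params.media_inner_radius) & (r < params.media_outer_radius)] = 1.0
    img[ch["dcn"]][(r >= params.media_outer_radius) & (r < params.adventitia_outer_radius)] = 1.0

    centers = _place_nuclei(rng, params, c0)
    n_med = params.n_medial_nuclei
    n_pos = int(round(params.positive_nucleus_fraction * n_med))
    pos_medial = rng.choice(n_med, size=n_pos, replace=False)
    positive = np.zeros(len(centers), dtype=bool)
    positive[pos_medial] = True  # medial nuclei come first in `centers`

    nuclei_records = []
    for i, (cy, cx) in enumerate(centers):
        disk = (rows - cy) ** 2 + (cols - cx) ** 2 <= params.nucleus_radius ** 2
        img[ch["dapi"]][disk] = 1.0
        if positive[i]:
            img[ch["marker"]][disk] = 1.0
        rad = np.hypot(cy - c0, cx - c0)
        nuclei_records.append(
            {
                "id": i,
                "center": (float(cy), float(cx)),
                "medial": bool(
                    params.media_inner_radius <= rad < params.media_outer_radius
                ),
                "positive": bool(positive[i]),
            }
        )

    if np.isfinite(params.channel_snr):
        img += rng.normal(0.0, 1.0 / params.channel_snr, size=img.shape).astype(
            np.float32
        )
        np.clip(img, 0.0, None, out=img)

    truth = SynthTruth(
        params=dataclasses.asdict(params),
        nuclei=nuclei_records,
        ring_radii={
            "lumen": params.lumen_radius,
            "media_inner": params.media_inner_radius,
            "media_outer": params.media_outer_radius,
            "adventitia_outer": params.adventitia_outer_radius,
        },
        channel_roles=list(CHANNEL_ROLES),
    )
    return img, truth


def _place_nuclei(
    rng: np.random.Generator, params: SimImageParams, c0: float
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping nucleus centers (medial first)."""
    nr = params.nucleus_radius
    spans = [
        (params.media_inner_radius + nr, params.media_outer_radius - nr, params.n_medial_nuclei),
        # adventitial nuclei sit clear of the media edge so that their disks
        # do not graze the (dilated) ACTA2 annulus
        (params.media_outer_radius + 2 * nr + 2, params.adventitia_outer_radius - nr, params.n_outer_nuclei),
    ]
    centers: list[tuple[float, float]] = []
    for r_lo, r_hi, count in spans:
        if count and r_hi <= r_lo:
            raise NucleusPlacementError("layer too thin for the nucleus radius")
        for _ in range(count):
            for _attempt in range(params.placement_retries):
                rad = np.sqrt(rng.uniform(r_lo ** 2, r_hi ** 2))
                ang = rng.uniform(0.0, 2.0 * np.pi)
                cy, cx = c0 + rad * np.sin(ang), c0 + rad * np.cos(ang)
                if all(np.hypot(cy - y, cx - x) > 2.0 * nr + 1.0 for y, x in centers):
                    centers.append((cy, cx))
                    break
            else:
                raise NucleusPlacementError(
                    f"could not place nucleus after {params.placement_retries} retries"
                )
    return centers
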