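"""Synthetic indigo-fermentation batches with planted phenotype causality.

The generator emulates the statistical structure of a small-scale sukumo
(composted *Polygonum tinctorium* leaf) fermentation study: four batches
prepared with different pretreatments (hot/cold water, with/without alkaline
wood-ash extract), maintained at 26 degC between pH 9.67 and 11.2 with
Ca(OH)2, with 1 g wheat-bran pulses on days 5, 19, 51, 85 and 194, sampled
daily during days 1-7 and sparsely to day 209, and sequenced to depths of
1e4-1e5 reads.

The moving parts, in the order the data are generated:

1.  **Environment** — pH declines by microbial acid production and is reset
    toward the ceiling by simulated Ca(OH)2 additions whenever it would cross
    the floor; ORP falls sigmoidally from a positive start to a deeply
    negative plateau; substrate pools (labile sukumo nutrients, dead
    microbial cells, wheat bran) rise and decay on their own clocks.
2.  **Community succession** — a seeded discrete-time multiplicative
    (replicator-like) update.  Each taxon's daily log-fitness is its baseline
    plus a Gaussian pH kernel, a signed logistic ORP term, substrate-affinity
    terms, minus a self-crowding penalty, plus small noise; abundances are
    renormalised daily.  Aerobes fade as ORP falls; alkaliphilic anaerobes
    and lactic-acid bacteria take over — the succession the analysis assumes.
3.  **Reads** — multinomial draws at per-sample depths.
4.  **Gene content** — sparse background copy numbers per taxon, with a
    planted causal KO set strictly enriched in indigo-reducer taxa.
5.  **Dye phenotype** — dyeing intensity is a saturating (logistic) function
    of the community-weighted causal-KO abundance plus Gaussian noise,
    emitted as an L*a*b* triple (b* < 0, the blue direction) whose Euclidean
    norm equals the intensity.

Everything is deterministic under (design, params, seed); per-batch and
per-stage RNG substreams are derived by stable hashing so adding a batch or
stage never perturbs the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import LabColor, RGBImage, lab_to_srgb
from .community_metrics import FeatureTable, derive_seed
from .function_link import GenomeContent, PathwayMap

__all__ = [
    "TaxonSpec", "FermentationDesign", "BatchSpec", "EnvDynamicsParams",
    "EnvironmentSeries", "CausalFunctionModel", "SyntheticDataset",
    "simulate_environment", "simulate_community", "sample_reads",
    "assign_genome_content", "emit_dye_series", "render_swatch",
    "default_taxa", "default_design", "default_causal_model",
    "simulate_dataset", "SUBPATHWAY_CATALOG",
]

OXYGEN_CLASSES = ("aerobe", "facultative", "obligate_anaerobe")
ORP_DIRECTIONS = ("prefers_high", "prefers_low")
SUBSTRATES = ("labile", "dead_cells", "bran")

# Blue-leaning unit direction used to emit L*a*b* from an intensity norm.
_LAB_DIRECTION = np.array([0.79, 0.12, -0.60])
_LAB_DIRECTION = _LAB_DIRECTION / np.linalg.norm(_LAB_DIRECTION)

# Subpathways relevant to the fermentation's carbohydrate/redox economy.
SUBPATHWAY_CATALOG = {
    "Phosphotransferase system (PTS)": {"super_pathway": "Membrane transport", "category": "Environmental information processing"},
    "Starch and sucrose metabolism": {"super_pathway": "Carbohydrate metabolism", "category": "Metabolism"},
    "Nicotinate and nicotinamide metabolism": {"super_pathway": "Metabolism of cofactors and vitamins", "category": "Metabolism"},
    "Prokaryotic defense system": {"super_pathway": "Signaling and cellular processes", "category": "Protein families"},
    "Pyruvate metabolism": {"super_pathway": "Carbohydrate metabolism", "category": "Metabolism"},
    "Glycolysis / Gluconeogenesis": {"super_pathway": "Carbohydrate metabolism", "category": "Metabolism"},
    "Amino acid metabolism": {"super_pathway": "Amino acid metabolism", "category": "Metabolism"},
    "ABC transporters": {"super_pathway": "Membrane transport", "category": "Environmental information processing"},
    "Methane metabolism": {"super_pathway": "Energy metabolism", "category": "Metabolism"},
    "Cell motility": {"super_pathway": "Cell motility", "category": "Cellular processes"},
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonSpec:
    """Ecophysiological profile of one synthetic taxon."""

    taxon_id: str
    oxygen_class: str
    ph_optimum: float
    ph_width: float
    orp_midpoint: float
    orp_direction: str
    substrate_affinity: dict
    baseline_fitness: float = 0.0
    indigo_reducer: bool = False

    def __post_init__(self) -> None:
        if self.oxygen_class not in OXYGEN_CLASSES:
            raise ValueError(f"unknown oxygen_class {self.oxygen_class!r}")
        if self.orp_direction not in ORP_DIRECTIONS:
            raise ValueError(f"unknown orp_direction {self.orp_direction!r}")
        if self.ph_width <= 0:
            raise ValueError("ph_width must be > 0")
        for k, v in self.substrate_affinity.items():
            if k not in SUBSTRATES:
                raise ValueError(f"unknown substrate {k!r}")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"substrate affinity for {k!r} outside [0, 1]: {v}")


@dataclass(frozen=True)
class BatchSpec:
    batch_id: str
    pretreat_temp: float   # degC
    pretreat_ph: float


@dataclass(frozen=True)
class FermentationDesign:
    """Batch layout, maintenance rules and sampling schedule."""

    batches: tuple
    ph_floor: float = 9.67
    ph_ceiling: float = 11.2
    bran_days: tuple = (5, 19, 51, 85, 194)
    bran_amount: float = 1.0
    temperature: float = 26.0
    sampling_days: tuple = (1, 2, 3, 4, 5, 6, 7, 10, 16, 29, 49, 75, 209)
    read_depth_range: tuple = (10_000, 100_000)

    def __post_init__(self) -> None:
        if self.ph_floor >= self.ph_ceiling:
            raise ValueError("ph_floor must be < ph_ceiling")
        if list(self.bran_days) != sorted(self.bran_days):
            raise ValueError("bran_days must be sorted ascending")
        if list(self.sampling_days) != sorted(self.sampling_days):
            raise ValueError("sampling_days must be sorted ascending")
        lo, hi = self.read_depth_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid read_depth_range")


@dataclass(frozen=True)
class EnvDynamicsParams:
    """All environmental-forcing and community-update coefficients.

    Units: pH in pH units, ORP in mV, time constants in days, pools in
    arbitrary units (AU).  The ORP numbers (+100 mV start, -550 mV plateau,
    midpoint day 1.5) are configurable defaults for an alkaline vat whose
    redox falls within the first two days.
    """

    # environment
    acid_rate: float = 0.2            # pH units lost per day to acid production
    ph_noise_sd: float = 0.02
    orp_start: float = 100.0          # mV at day 0
    orp_plateau: float = -550.0       # mV asymptote
    orp_midpoint_day: float = 1.5
    orp_steepness_days: float = 0.6
    orp_noise_sd: float = 5.0
    bran_tau: float = 30.0            # bran consumed within ~1 month
    labile_init: float = 1.0
    labile_tau: float = 5.0
    dead_cells_peak: float = 0.6
    dead_cells_peak_day: float = 3.0
    dead_cells_sustained: float = 1.0  # ongoing turnover feeds the pool
    # community update
    ph_kernel_scale: float = 3.0
    orp_kernel_scale: float = 1.5
    orp_kernel_width: float = 120.0   # mV
    substrate_scale: float = 5.0
    density_penalty: float = 6.0   # self-crowding; keeps tens of taxa coexisting
    growth_noise_sd: float = 2.0   # strong daily demographic volatility

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"EnvDynamicsParams.{f.name} must be finite, got {v!r}")


@dataclass
class EnvironmentSeries:
    """Day-indexed environmental record for one batch.

    ``records``: DataFrame indexed by day with columns ph, orp, labile,
    dead_cells, bran, caoh2_added.
    """

    batch_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        days = self.records.index.to_numpy()
        if not (np.diff(days) > 0).all():
            raise ValueError("days must be strictly increasing")
        for col in ("labile", "dead_cells", "bran"):
            if (self.records[col] < 0).any():
                raise ValueError(f"substrate pool {col!r} went negative")


@dataclass(frozen=True)
class CausalFunctionModel:
    """How the planted causal KOs drive dyeing intensity.

    intensity = baseline + (saturation - baseline) * logistic(slope * s)
    + N(0, noise_sd), where s is the community-weighted total abundance of
    the causal KOs.
    """

    causal_kos: frozenset
    slope: float = 0.04
    baseline: float = 20.0
    saturation: float = 80.0
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.saturation <= self.baseline:
            raise ValueError("saturation must exceed baseline")

    @property
    def dynamic_range(self) -> float:
        """Attainable intensity span above the zero-signal point:
        (saturation - baseline)/2, since logistic(0) = 1/2."""
        return (self.saturation - self.baseline) / 2.0


@dataclass
class SyntheticDataset:
    """A complete generated study: data plus the planted ground truth."""

    feature_table: FeatureTable
    environment: list
    genome_content: GenomeContent
    dye_series: pd.DataFrame          # sample-indexed: batch_id, day, L, a, b, intensity
    annotations: pd.DataFrame         # KO-indexed: symbol, description, ec_numbers, nadp_dependent
    pathway_map: PathwayMap
    truth: dict                       # causal_kos, true_trajectories, seed


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def simulate_environment(
    design: FermentationDesign,
    params: EnvDynamicsParams = EnvDynamicsParams(),
    seed: int = 0,
    n_days: int | None = None,
) -> list[EnvironmentSeries]:
    """Daily environmental trajectories for every batch of a design.

    pH starts at the batch's pretreatment pH, declines by the acid-production
    rate, and is reset to the ceiling (a Ca(OH)2 addition, flagged) whenever
    it would cross the floor.  ORP follows a noisy falling sigmoid.  The bran
    pool jumps by ``bran_amount`` on each bran day and decays with time
    constant ``bran_tau``; labile sukumo substrate decays from its initial
    value; dead cells pulse after the pretreatment die-off.
    """
    last_day = n_days if n_days is not None else int(max(design.sampling_days))
    out = []
    for batch in design.batches:
        rng = np.random.default_rng(derive_seed(seed, "environment", batch.batch_id))
        days = np.arange(0, last_day + 1)
        ph = np.empty(len(days))
        caoh2 = np.zeros(len(days), dtype=bool)
        current = float(np.clip(batch.pretreat_ph, design.ph_floor, design.ph_ceiling))
        bran = np.empty(len(days))
        bran_level = 0.0
        decay = np.exp(-1.0 / params.bran_tau)
        for i, day in enumerate(days):
            if i > 0:
                step = params.acid_rate
                if params.ph_noise_sd > 0:
                    step += rng.normal(0.0, params.ph_noise_sd)
                current -= step
                if current < design.ph_floor:
                    current = design.ph_ceiling
                    caoh2[i] = True
                bran_level *= decay
            if day in design.bran_days:
                bran_level += design.bran_amount
            ph[i] = current
            bran[i] = bran_level
        orp = params.orp_plateau + (params.orp_start - params.orp_plateau) * _logistic(
            -(days - params.orp_midpoint_day) / params.orp_steepness_days)
        if params.orp_noise_sd > 0:
            orp = orp + rng.normal(0.0, params.orp_noise_sd, size=len(days))
        labile = params.labile_init * np.exp(-days / params.labile_tau)
        t0 = params.dead_cells_peak_day
        # pretreatment die-off hump plus a sustained turnover supply
        dead = (params.dead_cells_peak * (days / t0) * np.exp(1.0 - days / t0)
                + params.dead_cells_sustained * (1.0 - np.exp(-days / t0)))
        records = pd.DataFrame(
            {"ph": ph, "orp": orp, "labile": labile, "dead_cells": dead,
             "bran": bran, "caoh2_added": caoh2},
            index=pd.Index(days, name="day"),
        )
        out.append(EnvironmentSeries(batch_id=batch.batch_id, records=records))
    return out


def simulate_community(
    taxa: list[TaxonSpec],
    env: EnvironmentSeries,
    seed: int = 0,
    params: EnvDynamicsParams = EnvDynamicsParams(),
    init_abundance=None,
) -> pd.DataFrame:
    """Replicator-like daily succession under one batch's environment.

    Returns a taxa x day proportion DataFrame over the environment's days.
    Daily log-fitness of taxon i:

        baseline_i + a_ph * exp(-((ph - opt_i)/width_i)^2 / 2)
                   + a_orp * sigmoid(+/-(orp - mid_i)/w_orp)
                   + a_sub * sum_pools affinity_i(pool) * level(pool)
                   - penalty * x_i + N(0, sd)

    followed by multiplicative update and renormalisation.
    """
    if len(taxa) == 0 or len(env.records) == 0:
        raise ValueError("need at least one taxon and a nonempty environment")
    n = len(taxa)
    if init_abundance is None:
        x = np.full(n, 1.0 / n)
    else:
        x = np.asarray(init_abundance, dtype=float)
        if x.sum() <= 0:
            raise ValueError("initial abundances are all zero")
        x = x / x.sum()
    rng = np.random.default_rng(derive_seed(seed, "community", env.batch_id))

    opt = np.array([t.ph_optimum for t in taxa])
    width = np.array([t.ph_width for t in taxa])
    mid = np.array([t.orp_midpoint for t in taxa])
    sign = np.array([1.0 if t.orp_direction == "prefers_high" else -1.0 for t in taxa])
    base = np.array([t.baseline_fitness for t in taxa])
    aff = np.array([[t.substrate_affinity.get(s, 0.0) for s in SUBSTRATES] for t in taxa])

    days = env.records.index.to_numpy()
    traj = np.empty((n, len(days)))
    for j, day in enumerate(days):
        rec = env.records.loc[day]
        pools = np.array([rec["labile"], rec["dead_cells"], rec["bran"]])
        logfit = (
            base
            + params.ph_kernel_scale * np.exp(-0.5 * ((rec["ph"] - opt) / width) ** 2)
            + params.orp_kernel_scale * _logistic(sign * (rec["orp"] - mid) / params.orp_kernel_width)
            + params.substrate_scale * (aff @ pools)
            - params.density_penalty * x
        )
        if params.growth_noise_sd > 0:
            logfit = logfit + rng.normal(0.0, params.growth_noise_sd, size=n)
        x = x * np.exp(logfit)
        x = x / x.sum()
        traj[:, j] = x
    return pd.DataFrame(traj, index=[t.taxon_id for t in taxa],
                        columns=pd.Index(days, name="day"))


def sample_reads(
    trajectory: pd.DataFrame,
    depths,
    seed: int = 0,
    sample_ids=None,
    batch_id: str = "",
) -> pd.DataFrame:
    """Multinomial read counts at the trajectory's days.

    ``trajectory`` is taxa x days proportions (each column summing to 1);
    ``depths`` one integer per column.  Column sums of the output equal the
    depths exactly.
    """
    props = trajectory.to_numpy()
    if (props < 0).any():
        raise ValueError("negative proportion in trajectory")
    col_sums = props.sum(axis=0)
    if not np.allclose(col_sums, 1.0, atol=1e-9):
        raise ValueError("trajectory columns must sum to 1 within 1e-9")
    depths = np.asarray(depths, dtype=np.int64)
    if depths.shape != (trajectory.shape[1],):
        raise ValueError("need one depth per trajectory column")
    if (depths < 1).any():
        raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(derive_seed(seed, "reads", batch_id))
    cols = []
    for j in range(trajectory.shape[1]):
        p = props[:, j] / col_sums[j]
        cols.append(rng.multinomial(depths[j], p))
    counts = np.stack(cols, axis=1)
    columns = sample_ids if sample_ids is not None else trajectory.columns
    return pd.DataFrame(counts, index=trajectory.index, columns=columns)


def assign_genome_content(
    taxa: list[TaxonSpec],
    n_kos: int,
    causal: CausalFunctionModel,
    seed: int = 0,
    background_presence: float = 0.5,
    background_extra_rate: float = 0.3,
    enrichment_offset: float = 5.0,
) -> GenomeContent:
    """Sparse taxon x KO copy numbers with planted reducer enrichment.

    Background KOs are present in a taxon with probability
    ``background_presence`` at 1 + Poisson(background_extra_rate) copies.
    Every causal KO additionally carries extra copies in every indigo-reducer
    taxon — ``enrichment_offset`` scaled by a per-(taxon, KO) lognormal
    factor, mirroring the uneven gene dosage real reducer genomes show —
    so its reducer mean is strictly higher than its non-reducer mean by
    construction.
    """
    causal_ids = sorted(causal.causal_kos)
    if n_kos < len(causal_ids):
        raise ValueError("n_kos must be >= number of causal KOs")
    reducers = [t.indigo_reducer for t in taxa]
    if causal_ids and not any(reducers):
        raise ValueError("causal KO set is nonempty but no taxon is an indigo reducer")
    rng = np.random.default_rng(derive_seed(seed, "genome"))
    ko_ids = [f"K{i + 1:05d}" for i in range(n_kos)]
    # causal ids outside the K00001..K<n> run replace trailing background ids
    missing = [c for c in causal_ids if c not in set(ko_ids)]
    if missing:
        replaceable = [k for k in reversed(ko_ids) if k not in set(causal_ids)]
        for cid, victim in zip(missing, replaceable):
            ko_ids[ko_ids.index(victim)] = cid
    n_taxa = len(taxa)
    present = rng.random((n_taxa, n_kos)) < background_presence
    copies = present * (1 + rng.poisson(background_extra_rate, size=(n_taxa, n_kos)))
    copies = copies.astype(float)
    df = pd.DataFrame(copies, index=[t.taxon_id for t in taxa], columns=ko_ids)
    red_mask = np.array(reducers)
    # per-taxon reducer gene dosage, shared across the causal set: strong
    # reducers carry proportionally more of every causal KO
    dosage = rng.lognormal(0.0, 1.2, size=int(red_mask.sum()))
    for cid in causal_ids:
        df.loc[red_mask, cid] += enrichment_offset * dosage
    return GenomeContent(copies=df)


def emit_dye_series(
    trajectory: pd.DataFrame,
    genome: GenomeContent,
    causal: CausalFunctionModel,
    seed: int = 0,
    batch_id: str = "",
) -> pd.DataFrame:
    """Dyeing-intensity series driven by the planted causal KOs.

    Per day, the causal signal is s = sum over causal KOs and taxa of
    abundance x copy number; intensity = baseline + (saturation - baseline) *
    logistic(slope * s) + noise, clipped at 0 (flagged).  The emitted
    (L*, a*, b*) lies along a fixed blue-leaning direction (b* < 0) with
    Euclidean norm equal to the intensity to within 1e-6.
    """
    if trajectory.shape[1] == 0:
        raise ValueError("trajectory has no days")
    causal_ids = sorted(causal.causal_kos)
    copies = genome.copies.loc[trajectory.index, causal_ids] if causal_ids else None
    rng = np.random.default_rng(derive_seed(seed, "dye", batch_id))
    rows = []
    for day in trajectory.columns:
        ab = trajectory[day].to_numpy()
        s = float(ab @ copies.to_numpy().sum(axis=1)) if causal_ids else 0.0
        mean = causal.baseline + (causal.saturation - causal.baseline) * float(
            _logistic(causal.slope * s))
        noise = rng.normal(0.0, causal.noise_sd) if causal.noise_sd > 0 else 0.0
        intensity = mean + noise
        clipped = intensity < 0
        intensity = max(intensity, 0.0)
        L, a, b = intensity * _LAB_DIRECTION
        rows.append({"day": day, "L": L, "a": a, "b": b,
                     "intensity": intensity, "clipped": clipped,
                     "causal_signal": s})
    return pd.DataFrame(rows).set_index("day")


def render_swatch(
    lab: LabColor,
    size: int = 64,
    texture_noise_sd: float = 0.0,
    seed: int = 0,
    frame_fraction: float = 0.1,
) -> RGBImage:
    """Render a dyed-cloth swatch: interior at ``lab`` (plus per-pixel Lab
    noise), framed by a light undyed margin.

    Out-of-gamut colours are mapped to the nearest in-gamut sRGB value and
    flagged in the image provenance.
    """
    from skimage import color as _skcolor

    if size < 8:
        raise ValueError("size must be >= 8 pixels")
    rng = np.random.default_rng(seed)
    lab_img = np.empty((size, size, 3))
    lab_img[..., 0], lab_img[..., 1], lab_img[..., 2] = 95.0, 0.0, 2.0  # undyed frame
    fw = max(1, int(size * frame_fraction))
    interior = lab.as_array()[None, None, :] * np.ones((size - 2 * fw, size - 2 * fw, 1))
    if texture_noise_sd > 0:
        interior = interior + rng.normal(0.0, texture_noise_sd, size=interior.shape)
        interior[..., 0] = np.clip(interior[..., 0], 0.0, 100.0)
    lab_img[fw : size - fw, fw : size - fw, :] = interior
    rgb = _skcolor.lab2rgb(lab_img)
    out_of_gamut = bool((rgb < -1e-9).any() or (rgb > 1 + 1e-9).any())
    _, in_gamut = lab_to_srgb(lab)
    pixels = np.clip(np.round(np.clip(rgb, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)
    provenance = "synthetic swatch"
    if out_of_gamut or not in_gamut:
        provenance += "; out-of-gamut colour clipped to sRGB cube"
    return RGBImage(pixels=pixels, provenance=provenance)


# ---------------------------------------------------------------------------
# default study conditions and full-dataset orchestration
# ---------------------------------------------------------------------------

def default_design(n_batches: int = 4, sampling_days=None) -> FermentationDesign:
    """The study layout: four pretreatments (heat / control / high pH /
    heat + high pH), pH band 9.67-11.2, bran on days 5/19/51/85/194."""
    batch_specs = (
        BatchSpec("B1", pretreat_temp=60.0, pretreat_ph=9.8),
        BatchSpec("B2", pretreat_temp=25.0, pretreat_ph=9.7),
        BatchSpec("B3", pretreat_temp=25.0, pretreat_ph=10.7),
        BatchSpec("B4", pretreat_temp=60.0, pretreat_ph=10.7),
    )[:n_batches]
    kwargs = {}
    if sampling_days is not None:
        kwargs["sampling_days"] = tuple(sampling_days)
    return FermentationDesign(batches=batch_specs, **kwargs)


def default_taxa(n_taxa: int = 40, seed: int = 0, reducer_fraction: float = 0.25) -> list[TaxonSpec]:
    """A taxon catalog spanning the succession's guilds.

    Roughly one third early aerobes (prefer high ORP, moderate pH optimum),
    the rest facultative anaerobes / lactic-acid bacteria and obligate
    anaerobes (prefer low ORP, alkaline pH optima).  A ``reducer_fraction``
    of the catalog is flagged indigo-reducing: the anaerobic taxa best
    adapted to wheat bran, the guild the bran pulses recruit and sustain.
    """
    rng = np.random.default_rng(derive_seed(seed, "taxa"))
    taxa = []
    n_aerobe = max(2, n_taxa // 3)
    classes = ["aerobe"] * n_aerobe
    rest = n_taxa - n_aerobe
    classes += ["facultative"] * (rest // 2) + ["obligate_anaerobe"] * (rest - rest // 2)
    for i, oclass in enumerate(classes):
        if oclass == "aerobe":
            ph_opt = rng.uniform(8.8, 9.9)
            orp_dir = "prefers_high"
            aff = {"labile": rng.uniform(0.5, 1.0), "dead_cells": rng.uniform(0.0, 0.3),
                   "bran": rng.uniform(0.0, 0.2)}
        elif oclass == "facultative":
            ph_opt = rng.uniform(9.5, 10.8)
            orp_dir = "prefers_low"
            bran = rng.uniform(0.2, 1.0)
            # resource specialisation: bran adaptation trades off dead-cell use
            aff = {"labile": rng.uniform(0.2, 0.6),
                   "dead_cells": (1.0 - 0.8 * bran) * rng.uniform(0.5, 1.0),
                   "bran": bran}
        else:
            ph_opt = rng.uniform(9.8, 11.0)
            orp_dir = "prefers_low"
            bran = rng.uniform(0.0, 1.0)
            aff = {"labile": rng.uniform(0.0, 0.3),
                   "dead_cells": (1.0 - 0.8 * bran) * rng.uniform(0.6, 1.0),
                   "bran": bran}
        taxa.append(TaxonSpec(
            taxon_id=f"T{i + 1:03d}",
            oxygen_class=oclass,
            ph_optimum=float(ph_opt),
            ph_width=float(rng.uniform(0.4, 1.0)),
            orp_midpoint=float(rng.uniform(-350.0, -50.0)),
            orp_direction=orp_dir,
            substrate_affinity=aff,
            baseline_fitness=float(rng.normal(0.0, 0.1)),
            indigo_reducer=False,
        ))
    # reducers: the bran-adapted anaerobes (late-succession guild)
    n_reducers = max(1, int(round(reducer_fraction * n_taxa)))
    anaerobic = [t for t in taxa if t.oxygen_class != "aerobe"]
    ranked = sorted(anaerobic, key=lambda t: t.substrate_affinity["bran"], reverse=True)
    reducer_ids = {t.taxon_id for t in ranked[:n_reducers]}
    return [dataclasses.replace(t, indigo_reducer=(t.taxon_id in reducer_ids))
            for t in taxa]


def default_causal_model(
    n_kos: int = 300, n_causal: int = 5, noise_fraction: float = 0.1
) -> CausalFunctionModel:
    """Causal model with the last ``n_causal`` KO ids planted and noise_sd
    set to ``noise_fraction`` of the attainable intensity dynamic range."""
    causal = frozenset(f"K{n_kos - i:05d}" for i in range(n_causal))
    base = CausalFunctionModel(causal_kos=causal)
    return dataclasses.replace(base, noise_sd=noise_fraction * base.dynamic_range)


def _annotate_kos(ko_ids, causal_ids, seed: int) -> pd.DataFrame:
    """Synthetic KO annotations.  Causal KOs are NAD(P)-dependent
    oxidoreductases (EC 1.*); background KOs draw generic annotations, a
    minority of which are non-NAD(P) EC 1.* enzymes."""
    rng = np.random.default_rng(derive_seed(seed, "annotations"))
    oxido_descriptions = [
        "NADP-dependent alcohol dehydrogenase", "NAD-dependent lactate dehydrogenase",
        "NAD(P) transhydrogenase subunit", "NADP-dependent aldehyde dehydrogenase",
        "NAD-dependent formate dehydrogenase", "NADP-dependent glycerol dehydrogenase",
    ]
    generic = [
        ("2", "PTS system EIICB component"), ("3", "glucan 1,6-alpha-glucosidase"),
        ("2", "phosphotransferase"), ("4", "aldolase"), ("5", "isomerase"),
        ("6", "ligase"), ("3", "peptidase"), ("2", "glycosyltransferase"),
    ]
    rows = {}
    causal_set = set(causal_ids)
    for ko in ko_ids:
        if ko in causal_set:
            desc = oxido_descriptions[rng.integers(len(oxido_descriptions))]
            ec = f"1.{rng.integers(1, 9)}.1.{rng.integers(1, 99)}"
            rows[ko] = {"symbol": f"cau{ko[-3:]}", "description": desc,
                        "ec_numbers": ec, "nadp_dependent": True}
        elif rng.random() < 0.1:  # some non-NAD(P) class-1 enzymes
            ec = f"1.{rng.integers(1, 9)}.3.{rng.integers(1, 99)}"
            rows[ko] = {"symbol": f"oxi{ko[-3:]}", "description": "FAD-dependent oxidase",
                        "ec_numbers": ec, "nadp_dependent": False}
        else:
            cls, desc = generic[rng.integers(len(generic))]
            ec = f"{cls}.{rng.integers(1, 9)}.{rng.integers(1, 9)}.{rng.integers(1, 99)}"
            rows[ko] = {"symbol": f"bkg{ko[-3:]}", "description": desc,
                        "ec_numbers": ec, "nadp_dependent": False}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("ko_id")


def _map_pathways(ko_ids, causal_ids, seed: int) -> PathwayMap:
    """Assign each KO to 1-2 subpathways; causal KOs land in the
    carbohydrate/redox subpathways the phenotype screen highlights."""
    rng = np.random.default_rng(derive_seed(seed, "pathways"))
    names = list(SUBPATHWAY_CATALOG)
    causal_pool = names[:3]  # PTS, starch & sucrose, nicotinate
    mapping: dict[str, set[str]] = {}
    causal_set = set(causal_ids)
    for ko in ko_ids:
        if ko in causal_set:
            mapping[ko] = {causal_pool[rng.integers(len(causal_pool))]}
        elif rng.random() < 0.9:
            k = 1 + (rng.random() < 0.2)
            mapping[ko] = set(rng.choice(names, size=k, replace=False))
        # ~10% left unmapped -> "unclassified"
    return PathwayMap(ko_to_subpathways=mapping, subpathway_info=dict(SUBPATHWAY_CATALOG))


def _initial_abundance(taxa, batch: BatchSpec, seed: int,
                       aerobe_bias: float = 10.0) -> np.ndarray:
    """Pretreatment shapes the inoculum.

    The composted-leaf inoculum comes from an aerobic solid fermentation, so
    aerobes start ``aerobe_bias``-fold over-represented; the pretreatment pH
    then selects through each taxon's pH kernel, with seeded lognormal
    scatter.  Anaerobes only take over later, once the vat's ORP falls.
    """
    rng = np.random.default_rng(derive_seed(seed, "init", batch.batch_id))
    w = np.array([
        (aerobe_bias if t.oxygen_class == "aerobe" else 1.0)
        * np.exp(t.baseline_fitness - 0.5 * ((batch.pretreat_ph - t.ph_optimum) / t.ph_width) ** 2)
        for t in taxa
    ])
    w = w * rng.lognormal(0.0, 0.5, size=len(taxa))
    return w / w.sum()


def simulate_dataset(
    design: FermentationDesign | None = None,
    params: EnvDynamicsParams = EnvDynamicsParams(),
    causal: CausalFunctionModel | None = None,
    taxa: list[TaxonSpec] | None = None,
    n_kos: int = 300,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a full study: environments, succession, reads, gene content,
    dye phenotype, annotations, pathway map and the planted-truth sidecar."""
    if design is None:
        design = default_design()
    if taxa is None:
        taxa = default_taxa(seed=seed)
    if causal is None:
        causal = default_causal_model(n_kos=n_kos)

    environments = simulate_environment(design, params, seed)
    genome = assign_genome_content(taxa, n_kos, causal, seed)
    count_blocks, meta_rows, dye_rows = [], [], []
    trajectories = {}
    for batch, env in zip(design.batches, environments):
        init = _initial_abundance(taxa, batch, seed)
        traj = simulate_community(taxa, env, seed, params, init_abundance=init)
        trajectories[batch.batch_id] = traj
        sampled = traj[list(design.sampling_days)]
        rng = np.random.default_rng(derive_seed(seed, "depths", batch.batch_id))
        lo, hi = design.read_depth_range
        depths = rng.integers(lo, hi + 1, size=sampled.shape[1])
        sample_ids = [f"{batch.batch_id}D{int(d)}" for d in sampled.columns]
        counts = sample_reads(sampled, depths, seed, sample_ids=sample_ids,
                              batch_id=batch.batch_id)
        count_blocks.append(counts)
        dye = emit_dye_series(sampled, genome, causal, seed, batch_id=batch.batch_id)
        for sid, (day, row) in zip(sample_ids, dye.iterrows()):
            rec = env.records.loc[day]
            meta_rows.append({"sample_id": sid, "batch_id": batch.batch_id,
                              "day": int(day), "ph": float(rec["ph"]),
                              "orp": float(rec["orp"]),
                              "dye_intensity": float(row["intensity"])})
            dye_rows.append({"sample_id": sid, "batch_id": batch.batch_id,
                             "day": int(day), "L": float(row["L"]),
                             "a": float(row["a"]), "b": float(row["b"]),
                             "intensity": float(row["intensity"]),
                             "clipped": bool(row["clipped"])})
    counts = pd.concat(count_blocks, axis=1).fillna(0).astype(np.int64)
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = FeatureTable(counts=counts, sample_meta=sample_meta)
    dye_series = pd.DataFrame(dye_rows).set_index("sample_id")
    causal_ids = sorted(causal.causal_kos)
    return SyntheticDataset(
        feature_table=table,
        environment=environments,
        genome_content=genome,
        dye_series=dye_series,
        annotations=_annotate_kos(genome.kos, causal_ids, seed),
        pathway_map=_map_pathways(genome.kos, causal_ids, seed),
        truth={"causal_kos": set(causal_ids), "true_trajectories": trajectories,
               "seed": int(seed)},
    )
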