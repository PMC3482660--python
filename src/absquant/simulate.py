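"""Seeded synthetic ground truth and synthetic measurements.

The generator emulates the statistical structure of an absolute-
quantification study on fission yeast: per-class log-normal copies/cell
(5,110 mRNAs at a median of 2.4 copies, 1,557 lncRNAs mostly below 1 copy,
a handful of very abundant rRNA species), length- and mappability-weighted
Poisson read counts at a fixed sequencing depth, molecule-counter runs with
a multiplicative gain and spiked external controls, summed MS intensities
proportional to copies times the protein's MS-suitable peptide count,
hand-measured cell geometries, and a nitrogen-removal time course with a
declining total-RNA content per cell.  A quiescent condition is derived
from the proliferating truth by class-level scaling (mRNA to 18%, rRNA to
11.2%, protein to 51.7% of proliferating totals, volume to ~57%) with
per-gene log-normal jitter, preserving the high cross-condition
correlation.

Every output is a deterministic function of the configuration and its
seed, so each downstream analysis stage can be validated by parameter
recovery.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cellcycle import CLUSTERS
from .compare import TimeCourseTable
from .proteins import count_ms_suitable
from .rna import NCounterRun, ReadCountTable

__all__ = [
    "SimulationConfig",
    "Feature",
    "FeatureCatalog",
    "TruthTable",
    "PeriodicParams",
    "generate_catalog",
    "generate_truth",
    "generate_readcounts",
    "generate_simulated_reads",
    "generate_ncounter",
    "generate_ms",
    "generate_cells",
    "generate_timecourse",
    "write_outputs",
]

PROLIF = "proliferating"
QUIESCENT = "quiescent"
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# yeast-like residue frequencies would be overkill; uniform letters already
# give realistic tryptic peptide-count distributions for the mass window


def _sigma_from_cv(cv: float) -> float:
    """Log-normal sigma giving a multiplicative coefficient of variation cv."""
    return float(np.sqrt(np.log(1.0 + cv**2)))


@dataclass
class PeriodicParams:
    """Cell-cycle regulation parameters attached to a periodic mRNA."""

    cluster: str
    amplitudes: tuple[float, ...]


@dataclass
class Feature:
    id: str
    feature_class: str
    length_nt: int
    mappability: float = 1.0
    protein_sequence: str | None = None
    categories: frozenset = field(default_factory=frozenset)
    periodic: PeriodicParams | None = None


@dataclass
class FeatureCatalog:
    """The simulated "genome": features with class, length and mappability."""

    features: list[Feature]

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")
        for f in self.features:
            if f.length_nt < 1:
                raise ValueError(f"{f.id}: length_nt must be >= 1")
            if f.mappability <= 0:
                raise ValueError(f"{f.id}: mappability must be positive")
            if f.protein_sequence is not None and f.feature_class != "mRNA":
                raise ValueError(f"{f.id}: only mRNAs carry a protein sequence")

    def ids(self, feature_class: str | None = None) -> list[str]:
        return [f.id for f in self.features if feature_class in (None, f.feature_class)]

    def by_id(self) -> dict[str, Feature]:
        return {f.id: f for f in self.features}

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": f.id,
                "class": f.feature_class,
                "length_nt": f.length_nt,
                "mappability": f.mappability,
                "has_protein": f.protein_sequence is not None,
                "periodic_cluster": f.periodic.cluster if f.periodic else "",
            }
            for f in self.features
        ]
        return pd.DataFrame(rows).set_index("id")


@dataclass
class TruthTable:
    """True copies/cell per condition for RNA features and proteins."""

    rna: pd.DataFrame  # feature id x condition
    protein: pd.DataFrame  # protein (gene) id x condition

    def __post_init__(self) -> None:
        if (self.rna < 0).to_numpy().any() or (self.protein < 0).to_numpy().any():
            raise ValueError("copies/cell must be non-negative")

    def total(self, condition: str, ids: list[str]) -> float:
        return float(self.rna.loc[self.rna.index.intersection(ids), condition].sum())


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults mirror the measured system."""

    # class sizes
    n_mrna: int = 5110
    n_lncrna: int = 1557
    n_rrna: int = 4
    n_spike: int = 13
    n_anchors: int = 49
    n_protein_anchors: int = 39
    # per-class abundance law (log-normal, natural-log parameters)
    mrna_log_median: float = float(np.log(2.4))
    mrna_log_sd: float = 1.15
    lncrna_log_median: float = float(np.log(0.1))
    lncrna_log_sd: float = 1.4
    rrna_total: float = 802_000.0
    rrna_log_sd: float = 0.3
    # feature geometry
    mrna_length_log_median: float = float(np.log(1400.0))
    mrna_length_log_sd: float = 0.5
    lncrna_length_log_median: float = float(np.log(1000.0))
    lncrna_length_log_sd: float = 0.6
    mappability_log_sd: float = 0.1
    # sequencing: mappable reads per total-RNA library
    depth: float = 172_000_000.0
    score_slope: float = 1.0  # distortion exponent linking copies to read rate
    count_noise: bool = True  # False: expected (noise-free) read counts
    # molecule counter
    ncounter_gain: float = 10.0
    ncounter_cv: float = 0.2
    ncounter_replicates: int = 3
    # proteome
    protein_fraction: float = 1.0  # fraction of mRNAs with a protein sequence
    protein_ratio_log_median: float = float(np.log(1633.0))
    protein_ratio_log_sd: float = 1.15
    ratio_saturation: bool = False
    saturation_midpoint: float = 50.0  # mRNA copies at which damping halves the ratio
    ms_response_cv: float = 0.4
    ms_technical_cv: float = 0.05
    ms_intensity_scale: float = 1.0
    ms_replicates: int = 2
    # cell cycle
    periodic_fraction: float = 241.0 / 5110.0
    n_experiments: int = 6
    amplitude_log_median: float = float(np.log(3.0))
    amplitude_log_sd: float = 0.5
    # quiescence scaling
    quiescence_mrna_scale: float = 0.18
    quiescence_lncrna_scale: float = 0.18
    quiescence_rrna_scale: float = 0.112
    quiescence_protein_scale: float = 0.517
    quiescence_volume_scale: float = 0.5714
    quiescence_jitter_sd: float = 0.3
    # cell geometry (um)
    n_cells: int = 260
    prolif_length_mean: float = 10.8
    prolif_length_sd: float = 1.4
    diameter_mean: float = 3.85
    diameter_sd: float = 0.15
    # quiescence-entry time course (hours)
    timepoints: tuple[float, ...] = (0, 0.5, 1, 2, 3, 4, 6, 9, 12, 16, 20, 24, 48, 72, 120, 168)
    decay_halftime_log_median: float = float(np.log(4.0))
    decay_halftime_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_rrna", "n_spike", "n_anchors", "n_protein_anchors", "n_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "mrna_log_sd", "lncrna_log_sd", "rrna_log_sd", "mappability_log_sd",
            "ncounter_cv", "ms_response_cv", "ms_technical_cv", "protein_ratio_log_sd", "quiescence_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for name in ("quiescence_mrna_scale", "quiescence_lncrna_scale", "quiescence_rrna_scale"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.protein_fraction <= 1:
            raise ValueError("protein_fraction must be in [0, 1]")
        times = np.asarray(self.timepoints, dtype=float)
        if len(times) and (times[0] != 0 or np.any(np.diff(times) <= 0)):
            raise ValueError("timepoints must start at 0 and be strictly increasing")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        key = zlib.crc32(stream.encode())  # stable across processes, unlike hash()
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["timepoints"] = list(d["timepoints"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        return cls(**d)


def _random_proteins(rng: np.random.Generator, lengths_aa: np.ndarray) -> list[str]:
    total = int(lengths_aa.sum())
    letters = rng.choice(AMINO_ACIDS, size=total)
    out, pos = [], 0
    for n in lengths_aa:
        out.append("".join(letters[pos : pos + n]))
        pos += n
    return out


def generate_catalog(config: SimulationConfig) -> FeatureCatalog:
    """Draw the feature catalog: classes, lengths, mappability, proteins."""
    rng = config.rng("catalog")
    features: list[Feature] = []

    mrna_len = np.maximum(
        90,
        rng.lognormal(config.mrna_length_log_median, config.mrna_length_log_sd, config.n_mrna).astype(int),
    )
    mappability = rng.lognormal(0.0, config.mappability_log_sd, config.n_mrna)
    has_protein = rng.random(config.n_mrna) < config.protein_fraction
    is_periodic = rng.random(config.n_mrna) < config.periodic_fraction
    prot_len = np.maximum(60, mrna_len // 3)
    sequences = _random_proteins(rng, prot_len)
    sigma_a = config.amplitude_log_sd
    for i in range(config.n_mrna):
        periodic = None
        if is_periodic[i]:
            amps = np.maximum(1.0, rng.lognormal(config.amplitude_log_median, sigma_a, config.n_experiments))
            periodic = PeriodicParams(cluster=str(rng.choice(CLUSTERS)), amplitudes=tuple(amps))
        features.append(
            Feature(
                id=f"mrna_{i:04d}",
                feature_class="mRNA",
                length_nt=int(mrna_len[i]),
                mappability=float(mappability[i]),
                protein_sequence=sequences[i] if has_protein[i] else None,
                periodic=periodic,
            )
        )

    lnc_len = np.maximum(
        90,
        rng.lognormal(config.lncrna_length_log_median, config.lncrna_length_log_sd, config.n_lncrna).astype(int),
    )
    lnc_map = rng.lognormal(0.0, config.mappability_log_sd, config.n_lncrna)
    for i in range(config.n_lncrna):
        features.append(
            Feature(
                id=f"lnc_{i:04d}",
                feature_class="lncRNA",
                length_nt=int(lnc_len[i]),
                mappability=float(lnc_map[i]),
            )
        )

    rrna_lengths = [1800, 3400, 158, 121]
    for i in range(config.n_rrna):
        features.append(
            Feature(id=f"rrna_{i}", feature_class="rRNA", length_nt=rrna_lengths[i % 4], mappability=1.0)
        )
    for i in range(config.n_spike):
        features.append(Feature(id=f"spike_{i:02d}", feature_class="spike", length_nt=1000))
    return FeatureCatalog(features)


def generate_truth(catalog: FeatureCatalog, config: SimulationConfig) -> TruthTable:
    """Draw true copies/cell for both conditions, RNA and protein."""
    rng = config.rng("truth")
    rows: dict[str, float] = {}
    for f in catalog.features:
        if f.feature_class == "mRNA":
            rows[f.id] = rng.lognormal(config.mrna_log_median, config.mrna_log_sd)
        elif f.feature_class == "lncRNA":
            rows[f.id] = rng.lognormal(config.lncrna_log_median, config.lncrna_log_sd)
        elif f.feature_class == "rRNA":
            n = max(config.n_rrna, 1)
            rows[f.id] = rng.lognormal(np.log(config.rrna_total / n), config.rrna_log_sd)
        else:  # spikes live in the nCounter run, not in cells
            continue
    prolif = pd.Series(rows, dtype=float)

    scale = pd.Series(1.0, index=prolif.index)
    classes = {f.id: f.feature_class for f in catalog.features}
    cls = prolif.index.map(classes)
    scale[np.asarray(cls) == "mRNA"] = config.quiescence_mrna_scale
    scale[np.asarray(cls) == "lncRNA"] = config.quiescence_lncrna_scale
    scale[np.asarray(cls) == "rRNA"] = config.quiescence_rrna_scale
    jitter_sigma = config.quiescence_jitter_sd
    jitter = np.exp(rng.normal(-0.5 * jitter_sigma**2, jitter_sigma, len(prolif))) if jitter_sigma > 0 else 1.0
    quiescent = prolif * scale * jitter
    rna = pd.DataFrame({PROLIF: prolif, QUIESCENT: quiescent})

    protein_ids = [f.id for f in catalog.features if f.protein_sequence is not None]
    mrna_copies = prolif.reindex(protein_ids)
    if config.protein_ratio_log_sd > 0:
        ratio = rng.lognormal(config.protein_ratio_log_median, config.protein_ratio_log_sd, len(protein_ids))
    else:
        ratio = np.full(len(protein_ids), np.exp(config.protein_ratio_log_median))
    if config.ratio_saturation:
        # logistic damping: high-mRNA genes get proportionally smaller ratios
        ratio = ratio / (1.0 + mrna_copies.to_numpy() / config.saturation_midpoint)
    prot_prolif = mrna_copies.to_numpy() * ratio
    pjit = (
        np.exp(rng.normal(-0.5 * jitter_sigma**2, jitter_sigma, len(protein_ids)))
        if jitter_sigma > 0
        else 1.0
    )
    prot_quiescent = prot_prolif * config.quiescence_protein_scale * pjit
    protein = pd.DataFrame({PROLIF: prot_prolif, QUIESCENT: prot_quiescent}, index=pd.Index(protein_ids))
    return TruthTable(rna=rna, protein=protein)


def _read_table(catalog: FeatureCatalog, weights: pd.Series, config: SimulationConfig,
                rng: np.random.Generator, sample_id: str) -> ReadCountTable:
    lengths = pd.Series({f.id: f.length_nt for f in catalog.features if f.id in weights.index})
    lengths = lengths.reindex(weights.index)
    total = weights.sum()
    if total <= 0:
        counts = np.zeros(len(weights))
    else:
        expected = config.depth * weights.to_numpy() / total
        counts = rng.poisson(expected) if config.count_noise else expected
    data = pd.DataFrame({"reads": counts, "length_nt": lengths.astype(int)}, index=weights.index)
    return ReadCountTable(sample_id=sample_id, data=data)


def generate_readcounts(
    truth: TruthTable,
    catalog: FeatureCatalog,
    config: SimulationConfig,
    condition: str = PROLIF,
    sample_id: str | None = None,
) -> ReadCountTable:
    """Poisson read counts with mean proportional to copies x length x mappability.

    Total expected reads equal the configured depth; spike features do not
    receive sequencing reads.
    """
    rng = config.rng(f"reads:{condition}:{sample_id or ''}")
    ids = [f.id for f in catalog.features if f.feature_class != "spike"]
    copies = truth.rna[condition].reindex(ids).fillna(0.0)
    meta = catalog.by_id()
    length_kb = pd.Series({i: meta[i].length_nt / 1000.0 for i in ids})
    mapp = pd.Series({i: meta[i].mappability for i in ids})
    weights = np.power(copies, config.score_slope) * length_kb * mapp
    weights[copies == 0] = 0.0
    return _read_table(catalog, weights, config, rng, sample_id or f"{condition}_reads")


def generate_simulated_reads(
    catalog: FeatureCatalog,
    config: SimulationConfig,
    genomic_copies: pd.Series | None = None,
    sample_id: str = "simulated",
) -> ReadCountTable:
    """Uniform-coverage control reads (the in-silico sequencing of the genome).

    Every feature contributes reads in proportion to length x mappability,
    optionally weighted by a genomic copy number (for emulating duplicated
    loci in a 'DNA' library).
    """
    rng = config.rng(f"simreads:{sample_id}")
    ids = [f.id for f in catalog.features if f.feature_class != "spike"]
    meta = catalog.by_id()
    weights = pd.Series({i: meta[i].length_nt / 1000.0 * meta[i].mappability for i in ids})
    if genomic_copies is not None:
        weights = weights * genomic_copies.reindex(weights.index).fillna(1.0)
    return _read_table(catalog, weights, config, rng, sample_id)


def generate_ncounter(
    truth: TruthTable,
    config: SimulationConfig,
    condition: str = PROLIF,
) -> NCounterRun:
    """Molecule-counter run: anchors plus spikes, with gain and noise.

    Counts are ``gain x copies x`` log-normal noise per replicate.  Anchors
    are mRNAs quantile-spaced across the abundance range; spike copies are
    log-spaced to cover (and slightly exceed) the anchor range.
    """
    rng = config.rng(f"ncounter:{condition}")
    mrna = truth.rna.loc[truth.rna.index.str.startswith("mrna_"), condition]
    mrna = mrna[mrna > 0].sort_values()
    if len(mrna) < config.n_anchors:
        raise ValueError("not enough expressed mRNAs to pick anchors")
    pick = np.unique(np.linspace(0, len(mrna) - 1, config.n_anchors).round().astype(int))
    anchors = mrna.iloc[pick]
    n_spike = max(config.n_spike, 3)
    spike_copies = pd.Series(
        np.geomspace(0.8 * anchors.min(), 1.25 * anchors.max(), n_spike),
        index=[f"spike_{i:02d}" for i in range(n_spike)],
        name="known_copies",
    )
    probes = pd.concat([anchors, spike_copies])
    sigma = _sigma_from_cv(config.ncounter_cv)
    reps = {}
    run_of = {}
    for r in range(config.ncounter_replicates):
        noise = (
            np.exp(rng.normal(-0.5 * sigma**2, sigma, len(probes))) if sigma > 0 else np.ones(len(probes))
        )
        name = f"rep{r + 1}"
        reps[name] = config.ncounter_gain * probes.to_numpy() * noise
        run_of[name] = f"run{1 if r < (config.ncounter_replicates + 1) // 2 else 2}"
    counts = pd.DataFrame(reps, index=probes.index)
    return NCounterRun(
        counts=counts,
        spike_copies=spike_copies,
        anchor_ids=list(anchors.index),
        run_of_replicate=run_of,
    )


@dataclass
class MSIntensityTable:
    """Summed per-protein precursor intensities with anchor annotations."""

    condition: str
    intensities: pd.DataFrame  # protein x replicate
    n_ms_suitable: pd.Series
    anchor_copies: pd.Series  # known copies/cell for the anchor proteins


def generate_ms(
    truth: TruthTable,
    catalog: FeatureCatalog,
    config: SimulationConfig,
    condition: str = PROLIF,
) -> MSIntensityTable:
    """Summed MS intensities: copies x MS-suitable peptide count x response.

    Each protein carries a fixed log-normal response factor (ionization and
    recovery efficiency) shared across replicates, plus per-replicate
    multiplicative noise.  Proteins without any MS-suitable peptide are
    excluded with a warning.  Anchor proteins (quantile-spaced across the
    abundance range) come with their known copies/cell.
    """
    rng = config.rng(f"ms:{condition}")
    seqs = {f.id: f.protein_sequence for f in catalog.features if f.protein_sequence is not None}
    ids = [i for i in truth.protein.index if i in seqs]
    n_pep = pd.Series({i: count_ms_suitable(seqs[i]) for i in ids})
    zero = n_pep[n_pep == 0]
    if len(zero):
        warnings.warn(f"{len(zero)} protein(s) with no MS-suitable peptide are undetectable", stacklevel=2)
    keep = n_pep.index[n_pep > 0]
    copies = truth.protein.loc[keep, condition]
    sigma_resp = _sigma_from_cv(config.ms_response_cv)
    response = (
        np.exp(rng.normal(-0.5 * sigma_resp**2, sigma_resp, len(keep))) if sigma_resp > 0 else np.ones(len(keep))
    )
    base = config.ms_intensity_scale * copies.to_numpy() * n_pep[keep].to_numpy() * response
    rep_sigma = _sigma_from_cv(config.ms_technical_cv)  # technical spread on top of the response factor
    cols = {}
    for r in range(config.ms_replicates):
        tech = np.exp(rng.normal(-0.5 * rep_sigma**2, rep_sigma, len(keep))) if rep_sigma > 0 else 1.0
        cols[f"rep{r + 1}"] = base * tech
    intensities = pd.DataFrame(cols, index=keep)

    detected = copies[copies > 0].sort_values()
    n_anchor = min(config.n_protein_anchors, len(detected))
    pick = np.unique(np.linspace(0, len(detected) - 1, n_anchor).round().astype(int))
    anchor_copies = detected.iloc[pick].rename("known_copies")
    return MSIntensityTable(
        condition=condition,
        intensities=intensities,
        n_ms_suitable=n_pep[keep],
        anchor_copies=anchor_copies,
    )


def generate_cells(config: SimulationConfig) -> pd.DataFrame:
    """Hand-measured cell lengths and widths for both conditions.

    Quiescent cells keep the proliferating diameter but are shorter, with
    the median quiescent volume set to ``quiescence_volume_scale`` times
    the proliferating median.
    """
    rng = config.rng("cells")
    n = config.n_cells
    rows = []
    d_p = np.maximum(1.0, rng.normal(config.diameter_mean, config.diameter_sd, n))
    l_p = np.maximum(d_p, rng.normal(config.prolif_length_mean, config.prolif_length_sd, n))
    # target quiescent length from the volume identity V = pi D^2 (L - D/3) / 4
    bracket_p = config.prolif_length_mean - config.diameter_mean / 3.0
    l_q_mean = config.quiescence_volume_scale * bracket_p + config.diameter_mean / 3.0
    d_q = np.maximum(1.0, rng.normal(config.diameter_mean, config.diameter_sd, n))
    l_q = np.maximum(d_q, rng.normal(l_q_mean, config.prolif_length_sd * l_q_mean / config.prolif_length_mean, n))
    for i in range(n):
        rows.append({"cell_id": f"p{i:03d}", "condition": PROLIF, "length_um": l_p[i], "width_um": d_p[i]})
        rows.append({"cell_id": f"q{i:03d}", "condition": QUIESCENT, "length_um": l_q[i], "width_um": d_q[i]})
    return pd.DataFrame(rows).set_index("cell_id")


def generate_timecourse(
    truth: TruthTable,
    config: SimulationConfig,
    n_genes: int | None = None,
) -> tuple[TimeCourseTable, pd.DataFrame]:
    """Quiescence-entry time course with total-RNA content fractions.

    Each mRNA decays exponentially from its proliferating toward its
    quiescent level with a per-gene half-time.  The reported per-gene
    ratios are globally renormalized (each time point divided by the
    population-average change), mimicking relative measurements that are
    blind to the total-RNA decline; the content fraction per time point is
    what restores the absolute scale.  Returns the relative table plus the
    true absolute profiles for validation.
    """
    rng = config.rng("timecourse")
    times = np.asarray(config.timepoints, dtype=float)
    mrna = truth.rna[truth.rna.index.str.startswith("mrna_")]
    if n_genes is not None:
        mrna = mrna.iloc[:n_genes]
    start = mrna[PROLIF].to_numpy()[:, None]
    end = mrna[QUIESCENT].to_numpy()[:, None]
    half = rng.lognormal(config.decay_halftime_log_median, config.decay_halftime_log_sd, len(mrna))[:, None]
    decay = np.exp(-np.log(2.0) * times[None, :] / half)
    absolute = end + (start - end) * decay
    true_profiles = pd.DataFrame(absolute, index=mrna.index, columns=times)
    content = true_profiles.sum(axis=0) / true_profiles.iloc[:, 0].sum()
    content.name = "content_fraction"
    per_gene = true_profiles.div(true_profiles.iloc[:, 0], axis=0)
    relative = per_gene.div(content, axis=1)  # what a globally normalized assay reports
    return TimeCourseTable(ratios=relative, content_fraction=content), true_profiles


def write_outputs(outdir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Run the full generator and write TSV/FASTA/YAML outputs to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = generate_catalog(config)
    truth = generate_truth(catalog, config)
    paths: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t")
        paths[name] = p

    save("catalog", catalog.frame())
    save("truth_rna", truth.rna)
    save("truth_protein", truth.protein)
    for cond in (PROLIF, QUIESCENT):
        save(f"reads_{cond}", generate_readcounts(truth, catalog, config, cond).data)
        run = generate_ncounter(truth, config, cond)
        save(f"ncounter_{cond}", run.counts)
        save(f"spikes_{cond}", run.spike_copies.to_frame())
        ms = generate_ms(truth, catalog, config, cond)
        save(f"ms_intensities_{cond}", ms.intensities.join(ms.n_ms_suitable.rename("n_ms_suitable")))
        save(f"ms_anchors_{cond}", ms.anchor_copies.to_frame())
    save("simulated_reads", generate_simulated_reads(catalog, config).data)
    save("cells", generate_cells(config))
    tc, _ = generate_timecourse(truth, config)
    save("timecourse_ratios", tc.ratios)
    save("timecourse_content", tc.content_fraction.to_frame())

    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(f.protein_sequence), id=f.id, description="")
        for f in catalog.features
        if f.protein_sequence is not None
    ]
    fasta = outdir / "proteome.fasta"
    SeqIO.write(records, fasta, "fasta")
    paths["proteome"] = fasta
    config.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths
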