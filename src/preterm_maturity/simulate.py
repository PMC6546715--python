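"""Synthetic longitudinal preterm-infant cohorts.

Generates the three inputs every downstream stage consumes — sample metadata,
an OTU count table, and a serum-metabolite panel — with the statistical
structure the analysis assumes:

* two growth groups (appropriate growth vs growth failure), weekly stool and
  serum sampling from the first postnatal week (study week 0) through week 9,
  with postmenstrual age (PMA) = birth gestational age + chronologic age;
* age-discriminatory taxa whose expected relative abundance follows
  monotone logistic trajectories in PMA (saturating colonization), the
  remainder flat; counts drawn Dirichlet-multinomial with log-normal library
  sizes, so every column sums to its drawn library size;
* age-discriminatory metabolites linear in PMA on the log2 scale, plus
  Gaussian noise, centered additive batch offsets, limit-of-detection
  censoring to zero, and missing-at-random masking of whole samples
  (emulating insufficient serum volume);
* a plantable maturation delay: for growth-failure samples every
  age-discriminatory trajectory is evaluated at PMA − delay_weeks, a
  horizontal time shift, so "delayed maturation" is literally recoverable as
  negative relative maturity.  With delay_weeks = 0 the two groups share one
  generating distribution (an exact null).

All randomness flows from the single integer seed through named sub-streams,
one per table, so regenerating any one table is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from .errors import ConfigurationError
from .metabolome import MetaboliteTable
from .microbiome import CountTable, write_count_table

_FAMILIES = [
    ("Enterobacteriaceae", ["Escherichia", "Klebsiella", "Enterobacter", "Serratia", "Citrobacter"]),
    ("Staphylococcaceae", ["Staphylococcus"]),
    ("Streptococcaceae", ["Streptococcus", "Lactococcus"]),
    ("Veillonellaceae", ["Veillonella"]),
    ("Peptostreptococcaceae", ["Romboutsia", ""]),
    ("Lachnospiraceae", ["Blautia", ""]),
    ("Clostridiaceae", ["Clostridium"]),
    ("Bifidobacteriaceae", ["Bifidobacterium"]),
    ("Enterococcaceae", ["Enterococcus", ""]),
    ("Micrococcaceae", ["Rothia"]),
    ("Bacillaceae", ["Bacillus"]),
]

_ACYL_CHAINS = [
    "C2", "C3", "C4", "C5", "C5:1", "C5-OH", "C6", "C6:1", "C8", "C8:1",
    "C10", "C10:2", "C12", "C12:1", "C14", "C14:1", "C16", "C16:1", "C18",
    "C18:1", "C18:2", "C20", "C20:4", "C4-DC", "C5-DC",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort generating conditions.

    Defaults emulate the study design: 58 analyzed infants of whom 36 have
    growth failure, birth gestational ages 23–27 weeks, stool/serum sampled at
    study weeks 0–9, ~100 retained OTUs of which 21 are age-discriminatory,
    a 45-metabolite acylcarnitine-style panel with 8 age-discriminatory
    members, library sizes log-normal around the study's median read depth
    (42,546), five metabolomics batches, and a 3-week planted maturation
    delay in the growth-failure group.
    """

    n_infants: int = 58
    prop_growth_failure: float = 36 / 58
    ga_birth_range: tuple[float, float] = (23.0, 27.0)
    sampling_weeks: tuple[int, ...] = tuple(range(10))
    n_taxa: int = 100
    n_age_taxa: int = 21
    delay_weeks: float = 3.0
    library_size_log_mean: float = float(np.log(42546.0))
    library_size_log_sd: float = 0.55
    dispersion: float = 50.0
    n_metabolites: int = 45
    n_age_metabolites: int = 8
    metab_noise_sd: float = 0.5
    lod_quantile: float = 0.05
    missing_frac: float = 0.05
    batch_count: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_infants", self.n_infants >= 1),
            ("prop_growth_failure", 0 <= self.prop_growth_failure <= 1),
            ("ga_birth_range", self.ga_birth_range[0] <= self.ga_birth_range[1]),
            ("sampling_weeks", len(self.sampling_weeks) >= 1),
            ("n_taxa", self.n_taxa >= 1),
            ("n_age_taxa", 0 <= self.n_age_taxa <= self.n_taxa),
            ("delay_weeks", self.delay_weeks >= 0),
            ("dispersion", self.dispersion > 0),
            ("n_metabolites", self.n_metabolites >= 1),
            ("n_age_metabolites", 0 <= self.n_age_metabolites <= self.n_metabolites),
            ("metab_noise_sd", self.metab_noise_sd >= 0),
            ("lod_quantile", 0 <= self.lod_quantile < 1),
            ("missing_frac", 0 <= self.missing_frac < 1),
            ("batch_count", self.batch_count >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(
                    f"invalid SimulationConfig field {name}={getattr(self, name)!r}"
                )


@dataclass(frozen=True)
class InfantProfile:
    """Per-infant ground truth: birth gestational age, fixed growth group,
    and the weight-z trajectory over the sampled weeks."""

    infant_id: str
    ga_birth: float
    group: str
    weight_z_trajectory: tuple[float, ...]


def _stream(config: SimulationConfig, name: str) -> np.random.Generator:
    """Named deterministic sub-stream of the config seed."""
    tag = {"metadata": 1, "counts": 2, "metabolites": 3, "truth": 4}[name]
    return np.random.default_rng(np.random.SeedSequence((config.seed, tag)))


def generate_metadata(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[InfantProfile]]:
    """One metadata row per infant x sampled week.

    Growth-failure infants receive a declining weight-z trajectory,
    appropriate-growth infants a stable one.  PMA = birth gestational age +
    chronologic age, where study week 0 is the first postnatal week and weeks
    1..9 resume once full enteral feeding is reached (4–6 chronologic weeks
    after birth).
    """
    rng = _stream(config, "metadata")
    n = config.n_infants
    n_gf = int(round(n * config.prop_growth_failure))
    gf_idx = set(rng.choice(n, size=n_gf, replace=False).tolist())
    weeks = list(config.sampling_weeks)

    profiles: list[InfantProfile] = []
    rows = []
    for i in range(n):
        infant_id = f"I{i + 1:03d}"
        ga = float(np.round(rng.uniform(*config.ga_birth_range), 1))
        group = "growth_failure" if i in gf_idx else "appropriate"
        feed_week = int(rng.integers(4, 7))  # chronologic weeks to full feeds
        z0 = float(rng.normal(-0.5, 0.3))
        slope = float(rng.normal(-0.20, 0.04)) if group == "growth_failure" else float(
            rng.normal(0.0, 0.02)
        )
        zs = []
        for w in weeks:
            chron = 0.5 if w == 0 else feed_week + (w - 1)
            pma = ga + chron
            z = z0 + slope * w + float(rng.normal(0, 0.05))
            zs.append(z)
            rows.append(
                {
                    "sample_id": f"{infant_id}W{w}",
                    "infant_id": infant_id,
                    "study_week": w,
                    "pma_weeks": round(pma, 2),
                    "group": group,
                    "weight_z": round(z, 3),
                    "batch": f"B{int(rng.integers(config.batch_count)) + 1}",
                    "full_enteral": w >= 1,
                }
            )
        profiles.append(InfantProfile(infant_id, ga, group, tuple(zs)))
    metadata = pd.DataFrame(rows).set_index("sample_id")
    return metadata, profiles


def _taxon_log_trajectories(config: SimulationConfig, rng: np.random.Generator):
    """Per-taxon log-abundance trajectory parameters.

    Age-discriminatory taxa follow logistic curves in PMA (alternating
    increasing/decreasing, midpoints spread over 27–41 weeks, amplitude 2–4
    log units); the remainder are flat at a log-normal baseline.
    """
    base = rng.normal(0.0, 1.0, size=config.n_taxa)
    amp = np.zeros(config.n_taxa)
    mid = np.full(config.n_taxa, 34.0)
    width = np.full(config.n_taxa, 2.0)
    for j in range(config.n_age_taxa):
        sign = 1.0 if j % 2 == 0 else -1.0
        amp[j] = sign * rng.uniform(2.0, 4.0)
        mid[j] = rng.uniform(27.0, 41.0)
        width[j] = rng.uniform(1.5, 3.0)
    return base, amp, mid, width


def _taxonomy_strings(config: SimulationConfig, rng: np.random.Generator):
    taxonomy = {}
    for j in range(config.n_taxa):
        fam, genera = _FAMILIES[j % len(_FAMILIES)]
        genus = genera[int(rng.integers(len(genera)))]
        tax = f"Bacteria;Phylum{j % 5 + 1};Class{j % 5 + 1};Order{j % 7 + 1};{fam}"
        if genus:
            tax += f";{genus}"
        taxonomy[f"OTU{j + 1:04d}"] = tax
    return taxonomy


def expected_composition(
    config: SimulationConfig, pma: float, group: str
) -> np.ndarray:
    """Expected relative-abundance vector at a given PMA for a group
    (the deterministic trajectory before Dirichlet-multinomial noise)."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    base, amp, mid, width = _taxon_log_trajectories(config, rng)
    t = pma - (config.delay_weeks if group == "growth_failure" else 0.0)
    logw = base + amp * expit((t - mid) / width)
    return softmax(logw)


def generate_counts(
    metadata: pd.DataFrame, config: SimulationConfig
) -> CountTable:
    """Dirichlet-multinomial OTU counts along the planted trajectories.

    Growth-failure samples are generated from the appropriate-growth
    trajectory evaluated at PMA − delay_weeks; column sums equal the drawn
    log-normal library sizes.
    """
    if metadata.empty:
        raise ConfigurationError("metadata is empty")
    rng = _stream(config, "counts")
    base, amp, mid, width = _taxon_log_trajectories(config, rng)
    taxonomy = _taxonomy_strings(config, rng)
    feature_ids = list(taxonomy)

    cols = {}
    for sample_id, row in metadata.iterrows():
        t = row["pma_weeks"] - (
            config.delay_weeks if row["group"] == "growth_failure" else 0.0
        )
        logw = base + amp * expit((t - mid) / width)
        p = softmax(logw)
        alpha = config.dispersion * p
        comp = rng.dirichlet(alpha)
        depth = int(
            np.round(
                np.exp(rng.normal(config.library_size_log_mean, config.library_size_log_sd))
            )
        )
        cols[sample_id] = rng.multinomial(max(depth, 1), comp)
    counts = pd.DataFrame(cols, index=feature_ids)
    return CountTable(counts, pd.Series(taxonomy))


def _metabolite_trajectories(config: SimulationConfig, rng: np.random.Generator):
    """Log2-intensity intercepts and PMA slopes.

    Age-discriminatory metabolites alternate decreasing (short/medium-chain
    acylcarnitine pattern) and increasing (long-chain pattern) linear trends;
    the rest are flat.
    """
    intercepts = rng.normal(6.0, 1.0, size=config.n_metabolites)
    slopes = np.zeros(config.n_metabolites)
    for j in range(config.n_age_metabolites):
        sign = -1.0 if j % 2 == 0 else 1.0
        slopes[j] = sign * rng.uniform(0.12, 0.30)
    return intercepts, slopes


def metabolite_ids(config: SimulationConfig) -> list[str]:
    ids = []
    for j in range(config.n_metabolites):
        chain = _ACYL_CHAINS[j % len(_ACYL_CHAINS)]
        suffix = "" if j < len(_ACYL_CHAINS) else f"-{j // len(_ACYL_CHAINS) + 1}"
        ids.append(f"{chain}{suffix} carnitine")
    return ids


def generate_metabolites(
    metadata: pd.DataFrame, config: SimulationConfig
) -> MetaboliteTable:
    """Linear-in-PMA log2 intensities with noise, centered batch offsets,
    limit-of-detection censoring to zero, and missing-at-random masking."""
    if metadata.empty:
        raise ConfigurationError("metadata is empty")
    rng = _stream(config, "metabolites")
    intercepts, slopes = _metabolite_trajectories(config, rng)
    ids = metabolite_ids(config)

    batches = sorted(metadata["batch"].unique())
    offsets = rng.normal(0.0, 0.3, size=(config.n_metabolites, len(batches)))
    offsets -= offsets.mean(axis=1, keepdims=True)  # centered so 1 batch => 0
    batch_col = {b: k for k, b in enumerate(batches)}

    t = metadata["pma_weeks"].to_numpy() - np.where(
        metadata["group"].to_numpy() == "growth_failure", config.delay_weeks, 0.0
    )
    log2v = intercepts[:, None] + slopes[:, None] * (t[None, :] - 34.0)
    log2v = log2v + offsets[:, [batch_col[b] for b in metadata["batch"]]]
    log2v = log2v + rng.normal(0.0, config.metab_noise_sd, size=log2v.shape)
    values = np.power(2.0, log2v)

    # limit-of-detection censoring: per metabolite, values below its
    # lod_quantile quantile become measured zeros
    if config.lod_quantile > 0:
        lod = np.quantile(values, config.lod_quantile, axis=1, keepdims=True)
        values = np.where(values < lod, 0.0, values)
    # missing-at-random mask: whole samples lose their panel (the
    # insufficient-serum-volume mechanism of targeted panels)
    if config.missing_frac > 0:
        mar = rng.uniform(size=values.shape[1]) < config.missing_frac
        values = np.where(mar[None, :], np.nan, values)

    frame = pd.DataFrame(values, index=ids, columns=metadata.index)
    return MetaboliteTable(
        frame,
        panel="targeted_AC_AA",
        batch=metadata["batch"].copy(),
    )


def generate_cohort(config: SimulationConfig):
    """Convenience: metadata + profiles + counts + metabolites + truth dict."""
    metadata, profiles = generate_metadata(config)
    counts = generate_counts(metadata, config)
    metabolites = generate_metabolites(metadata, config)
    truth = planted_truth(config)
    return metadata, profiles, counts, metabolites, truth


def planted_truth(config: SimulationConfig) -> dict:
    """Planted parameters, for test oracles."""
    rng_c = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    base, amp, mid, width = _taxon_log_trajectories(config, rng_c)
    rng_m = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    intercepts, slopes = _metabolite_trajectories(config, rng_m)
    return {
        "delay_weeks": config.delay_weeks,
        "age_taxa": [f"OTU{j + 1:04d}" for j in range(config.n_age_taxa)],
        "taxon_amplitude": amp.tolist(),
        "taxon_midpoint": mid.tolist(),
        "age_metabolites": metabolite_ids(config)[: config.n_age_metabolites],
        "metabolite_slopes": slopes.tolist(),
        "metabolite_intercepts": intercepts.tolist(),
    }


def write_cohort(config: SimulationConfig, out_dir) -> dict:
    """Write metadata TSV, counts TSV (with taxonomy column), metabolites
    CSV, and truth JSON under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata, profiles, counts, metabolites, truth = generate_cohort(config)
    paths = {
        "metadata": out / "metadata.tsv",
        "counts": out / "counts.tsv",
        "metabolites": out / "metabolites.csv",
        "truth": out / "truth.json",
    }
    metadata.to_csv(paths["metadata"], sep="\t")
    write_count_table(counts, paths["counts"])
    metabolites.values.to_csv(paths["metabolites"])
    truth = dict(truth, config=asdict(config))
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return {k: str(v) for k, v in paths.items()}
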