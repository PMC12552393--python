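"""Synthetic paired RAD/EpiRAD libraries and telomere tables with known truth.

The generator emulates a cross-sectional two-tissue study of turquoise
killifish (*Nothobranchius furzeri*): 32 individually housed fish (15 females,
17 males) sampled at three ages, with fin and gonad tissue from each, and two
sequencing libraries per tissue sample — a methylation-insensitive "RAD"
library (MspI) and a methylation-sensitive "EpiRAD" library (HpaII).  A locus
that is fully methylated in a sample is never cut by HpaII, so it drops out of
that sample's EpiRAD library; partially methylated loci retain reads in
proportion to the unmethylated cell fraction.

Every stage of the downstream analysis (CPM normalisation, locus retention,
zero-read methylation calling, proportion statistics, fin→gonad regressions)
can therefore be checked against the ground-truth state matrix generated here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

AGE_GROUPS = ("AGE1", "AGE2", "AGE3")
SEXES = ("F", "M")
TISSUES = ("fin", "gonad")
LIBRARY_TYPES = ("RAD", "EpiRAD")


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


class SimulationError(RuntimeError):
    """Raised when generation cannot proceed (e.g. no unmethylated loci left)."""


# Effective probability that a locus designated methylated (fully or partially)
# ends up with zero EpiRAD reads at default depth: fully methylated loci are
# always zero, and a partially methylated retained locus drops to zero with
# probability z ~= 0.0055 (measured once by simulation at the default
# configuration, 946/172297 over 80 replicates; see docs/methods.md,
# "Calibration"), giving (1 - partial_frac) + partial_frac * z.  Used to
# convert target *called* proportions into generating probabilities.
EFFECTIVE_CALL_RATE = 0.8011

# Target called methylation proportions (%) by tissue: fins carry an age trend
# (no sex effect), gonads a male surplus (no age trend).  Weighted means over
# the default design equal 1.36% (fins) and 2.15% (gonads) exactly.
_FIN_CALLED_PCT_BY_AGE = {"AGE1": 1.14, "AGE2": 1.36, "AGE3": 1.56}
_GONAD_CALLED_PCT_BY_SEX = {"F": 1.8525, "M": 2.4125}


def default_meth_prob() -> dict:
    """Per (tissue, sex, age) probability that a locus is methylation-designated.

    Calibrated so that the zero-read calling pipeline recovers mean called
    proportions of ~1.36% in fins and ~2.15% in gonads at default depth.
    """
    prob: dict = {t: {s: {} for s in SEXES} for t in TISSUES}
    for s in SEXES:
        for a in AGE_GROUPS:
            prob["fin"][s][a] = _FIN_CALLED_PCT_BY_AGE[a] / 100.0 / EFFECTIVE_CALL_RATE
            prob["gonad"][s][a] = _GONAD_CALLED_PCT_BY_SEX[s] / 100.0 / EFFECTIVE_CALL_RATE
    return prob


def default_fin_mean_kb() -> dict:
    """Fin telomere-median means (kb) per sex and age: AGE2 dip, female surplus."""
    return {
        "F": {"AGE1": 7.9, "AGE2": 7.0, "AGE3": 7.9},
        "M": {"AGE1": 7.3, "AGE2": 6.4, "AGE3": 7.3},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the design of the emulated experiment: 32 individuals
    (15 F / 17 M) across three age samplings of sizes 10/11/11, two tissues,
    paired RAD/EpiRAD libraries averaging 3.76M and 4.45M mapped reads.
    """

    n_individuals: int = 32
    n_females: int = 15
    age_group_sizes: tuple = (10, 11, 11)
    females_per_age: tuple = (5, 6, 4)
    n_loci: int = 8000
    mean_library_size_rad: float = 3.76e6
    mean_library_size_epirad: float = 4.45e6
    library_size_cv: float = 0.15
    locus_propensity_shape: float = 2.0
    meth_prob: dict = field(default_factory=default_meth_prob)
    partial_frac: float = 0.2
    partial_retention: float = 0.5
    fin_mean_kb: dict = field(default_factory=default_fin_mean_kb)
    fin_sd_kb: float = 0.9
    slope_b: float = 0.97
    male_offset_kb: float = -1.36
    resid_sd_kb: float = 0.75
    body_size_mean_mm: dict = field(default_factory=lambda: {"F": 45.0, "M": 50.0})
    body_size_sd_mm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        self.age_group_sizes = tuple(int(v) for v in self.age_group_sizes)
        self.females_per_age = tuple(int(v) for v in self.females_per_age)
        self.validate()

    def validate(self) -> None:
        if len(self.age_group_sizes) != 3 or len(self.females_per_age) != 3:
            raise ConfigError("age_group_sizes and females_per_age must have 3 entries")
        if sum(self.age_group_sizes) != self.n_individuals:
            raise ConfigError(
                f"age_group_sizes {self.age_group_sizes} must sum to "
                f"n_individuals={self.n_individuals}"
            )
        if sum(self.females_per_age) != self.n_females:
            raise ConfigError(
                f"females_per_age {self.females_per_age} must sum to "
                f"n_females={self.n_females}"
            )
        if self.n_females > self.n_individuals:
            raise ConfigError("n_females cannot exceed n_individuals")
        for g, f in zip(self.age_group_sizes, self.females_per_age):
            if f > g or f < 0:
                raise ConfigError("females_per_age entries must fit their age group")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be positive")
        for t in TISSUES:
            for s in SEXES:
                for a in AGE_GROUPS:
                    p = self.meth_prob[t][s][a]
                    if not 0.0 <= p <= 1.0:
                        raise ConfigError(f"meth_prob[{t}][{s}][{a}]={p} outside [0, 1]")
        for name in ("partial_frac", "partial_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not np.isfinite(self.slope_b):
            raise ConfigError("slope_b must be finite")
        if self.resid_sd_kb <= 0:
            raise ConfigError("resid_sd_kb must be > 0")
        if self.library_size_cv < 0:
            raise ConfigError("library_size_cv must be >= 0")
        if self.locus_propensity_shape <= 0:
            raise ConfigError("locus_propensity_shape must be > 0")

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_group_sizes"] = list(self.age_group_sizes)
        d["females_per_age"] = list(self.females_per_age)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def _streams(self):
        """Independent child generators: metadata, states, counts, telomeres."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        return [np.random.default_rng(c) for c in children]


@dataclass
class SimulatedDataset:
    """Bundle of one synthetic study replicate."""

    config: SimConfig
    meta: pd.DataFrame
    states: pd.DataFrame
    rad: pd.DataFrame
    epirad: pd.DataFrame
    telomeres: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.meta.to_csv(out / "meta.csv", index=False)
        self.rad.to_csv(out / "rad_counts.tsv", sep="\t", index_label="locus_id")
        self.epirad.to_csv(out / "epirad_counts.tsv", sep="\t", index_label="locus_id")
        self.telomeres.to_csv(out / "telomeres.csv", index=False)
        self.states.to_csv(out / "true_states.tsv", sep="\t", index_label="locus_id")
        self.config.to_yaml(out / "sim_config.yaml")


def simulate_metadata(config: SimConfig, rng=None) -> pd.DataFrame:
    """One row per library: 2 tissues x {RAD, EpiRAD} per individual.

    Sexes are allocated to age groups by the sacrifice schedule in the config;
    body sizes are Normal per sex; library sizes are gamma around the
    type-specific mean with CV ``library_size_cv``.
    """
    if rng is None:
        rng = config._streams()[0]
    inds = []
    idx = 0
    for age, g_size, g_f in zip(AGE_GROUPS, config.age_group_sizes, config.females_per_age):
        for j in range(g_size):
            idx += 1
            inds.append(
                {
                    "individual_id": f"I{idx:02d}",
                    "sex": "F" if j < g_f else "M",
                    "age_group": age,
                }
            )
    rows = []
    for ind in inds:
        body = rng.normal(config.body_size_mean_mm[ind["sex"]], config.body_size_sd_mm)
        body = max(body, 1.0)
        for tissue in TISSUES:
            for lib_type in LIBRARY_TYPES:
                mean_size = (
                    config.mean_library_size_rad
                    if lib_type == "RAD"
                    else config.mean_library_size_epirad
                )
                if config.library_size_cv > 0:
                    shape = 1.0 / config.library_size_cv**2
                    size = rng.gamma(shape, mean_size / shape)
                else:
                    size = mean_size
                rows.append(
                    {
                        **ind,
                        "tissue": tissue,
                        "library_type": lib_type,
                        "sample_id": f"{ind['individual_id']}_{tissue}",
                        "library_id": f"{ind['individual_id']}_{tissue}_{lib_type}",
                        "body_size_mm": round(body, 1),
                        "library_size": max(int(round(size)), 1),
                    }
                )
    return pd.DataFrame(rows)


def simulate_methylation_states(
    config: SimConfig, meta: pd.DataFrame, rng=None
) -> pd.DataFrame:
    """True per-(locus, sample) methylation state.

    0 = unmethylated, 1 = fully methylated, f in (0, 1) = fraction of cells
    methylated (partial).  Each locus is independently methylation-designated
    with the sample's ``meth_prob``; a designated locus becomes partial with
    probability ``partial_frac``, drawing f uniformly.
    """
    if rng is None:
        rng = config._streams()[1]
    samples = meta.drop_duplicates("sample_id")
    locus_ids = pd.Index([f"L{i+1:06d}" for i in range(config.n_loci)],
                         name="locus_id")
    states = np.zeros((config.n_loci, len(samples)), dtype=float)
    for j, (_, row) in enumerate(samples.iterrows()):
        p = config.meth_prob[row.tissue][row.sex][row.age_group]
        designated = rng.random(config.n_loci) < p
        partial = designated & (rng.random(config.n_loci) < config.partial_frac)
        col = designated.astype(float)
        k = int(partial.sum())
        if k:
            f = rng.random(k)
            f = np.clip(f, 1e-9, 1 - 1e-9)
            col[partial] = f
        states[:, j] = col
    return pd.DataFrame(states, index=locus_ids, columns=samples["sample_id"].tolist())


def simulate_read_counts(
    states: pd.DataFrame, meta: pd.DataFrame, config: SimConfig, rng=None
):
    """Paired count matrices (RAD, EpiRAD), loci x libraries.

    Per-locus capture propensities are drawn once (gamma, mean 1) and shared by
    every library — RAD/EpiRAD pairs come from one DNA aliquot, so capture bias
    is common.  RAD reads are multinomial over the raw propensities; EpiRAD
    propensities are zeroed for fully methylated loci and scaled by
    ``partial_retention * (1 - f)`` for partial ones before the draw.
    """
    if rng is None:
        rng = config._streams()[2]
    w = rng.gamma(config.locus_propensity_shape, 1.0 / config.locus_propensity_shape,
                  size=config.n_loci)
    w = np.maximum(w, 1e-12)
    s_arr = states.to_numpy()
    sample_ids = list(states.columns)
    rad_cols, epi_cols = {}, {}
    for _, row in meta.iterrows():
        j = sample_ids.index(row.sample_id)
        if row.library_type == "RAD":
            p = w / w.sum()
        else:
            s = s_arr[:, j]
            retention = np.where(
                s == 0.0, 1.0,
                np.where(s == 1.0, 0.0, config.partial_retention * (1.0 - s)),
            )
            eff = w * retention
            tot = eff.sum()
            if tot <= 0:
                raise SimulationError(
                    f"library {row.library_id}: every locus fully methylated, "
                    "no EpiRAD reads can be generated"
                )
            p = eff / tot
        counts = rng.multinomial(int(row.library_size), p)
        (rad_cols if row.library_type == "RAD" else epi_cols)[row.library_id] = counts
    rad = pd.DataFrame(rad_cols, index=states.index)
    epirad = pd.DataFrame(epi_cols, index=states.index)
    return rad, epirad


def simulate_telomeres(
    meta: pd.DataFrame, config: SimConfig, rng=None, max_retries: int = 100
) -> pd.DataFrame:
    """Telomere-length medians (kb) per individual x tissue.

    Fin medians are Normal per sex x age; gonad medians follow
    ``a + slope_b * fin + male_offset_kb * [male] + eps`` with the intercept
    chosen so female gonad means equal female fin means.  Non-positive draws
    are redrawn up to ``max_retries`` times.
    """
    if rng is None:
        rng = config._streams()[3]
    inds = meta.drop_duplicates("individual_id")[["individual_id", "sex", "age_group"]]
    # female-weighted fin mean fixes the regression intercept
    f_rows = inds[inds.sex == "F"]
    if len(f_rows):
        fin_mean_f = np.mean(
            [config.fin_mean_kb["F"][a] for a in f_rows.age_group]
        )
    else:
        fin_mean_f = np.mean([config.fin_mean_kb["M"][a] for a in inds.age_group])
    intercept = (1.0 - config.slope_b) * fin_mean_f

    def _draw_positive(draw):
        for _ in range(max_retries):
            v = draw()
            if v > 0:
                return v
        raise SimulationError("could not draw a positive telomere median")

    rows = []
    for _, ind in inds.iterrows():
        fin = _draw_positive(
            lambda: rng.normal(config.fin_mean_kb[ind.sex][ind.age_group], config.fin_sd_kb)
        )
        male = 1.0 if ind.sex == "M" else 0.0
        gonad = _draw_positive(
            lambda: intercept
            + config.slope_b * fin
            + config.male_offset_kb * male
            + rng.normal(0.0, config.resid_sd_kb)
        )
        for tissue, val in (("fin", fin), ("gonad", gonad)):
            rows.append(
                {
                    "individual_id": ind.individual_id,
                    "sex": ind.sex,
                    "age_group": ind.age_group,
                    "tissue": tissue,
                    "median_kb": val,
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one full replicate: metadata, truth, counts, telomeres."""
    rng_meta, rng_states, rng_counts, rng_telo = config._streams()
    meta = simulate_metadata(config, rng_meta)
    states = simulate_methylation_states(config, meta, rng_states)
    rad, epirad = simulate_read_counts(states, meta, config, rng_counts)
    telomeres = simulate_telomeres(meta, config, rng_telo)
    return SimulatedDataset(config, meta, states, rad, epirad, telomeres)
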