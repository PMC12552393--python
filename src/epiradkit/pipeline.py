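"""End-to-end orchestration: simulate/load -> call -> summarize -> model -> ordinate.

Every stage persists its artifact (TSV/CSV) before the next runs, so any
stage can be audited or re-run; the final machine-readable report only quotes
numbers already written to stage files.  All randomness flows from the single
configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, epirad, ordination, stats
from .simdata import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one input mode: an embedded :class:`SimConfig`, or paths to real
    count matrices, metadata and telomere tables.
    """

    sim: SimConfig | None = None
    rad_path: str | None = None
    epirad_path: str | None = None
    meta_path: str | None = None
    telomere_path: str | None = None
    cpm_threshold: float = epirad.DEFAULT_CPM_THRESHOLD
    sensitivity_thresholds: tuple = (7.0, 21.0)
    mds_axes: int = 2
    mds_metric: str = "euclidean"
    out_dir: str = "epiradkit_run"
    seed: int | None = None

    def __post_init__(self):
        real = [self.rad_path, self.epirad_path, self.meta_path]
        has_real = any(p is not None for p in real)
        if has_real and self.sim is not None:
            raise ValueError("provide either real-input paths or a SimConfig, not both")
        if not has_real and self.sim is None:
            raise ValueError("provide real-input paths or a SimConfig")
        if has_real and not all(p is not None for p in real):
            raise ValueError("real input needs rad_path, epirad_path and meta_path")
        if self.cpm_threshold <= 0:
            raise ValueError("cpm_threshold must be > 0")
        if self.sim is not None and self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "sensitivity_thresholds" in d:
            d["sensitivity_thresholds"] = tuple(d["sensitivity_thresholds"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        d["sensitivity_thresholds"] = list(self.sensitivity_thresholds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def summarize_proportions(
    values: pd.DataFrame, value_col: str, by=("tissue",)
) -> pd.DataFrame:
    """Mean, s.e. (sd/sqrt(n)), min, max per group of a tidy value table.

    Groups of size 1 get a missing s.e. (logged), never a zero.
    """
    if values.empty:
        raise ValueError("empty value table")
    rows = []
    for key, grp in values.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        v = grp[value_col].to_numpy(dtype=float)
        se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
        if len(v) == 1:
            logger.info("group %s has a single value; s.e. undefined", key)
        rows.append(
            {
                **dict(zip(by, key)),
                "n": len(v),
                "mean": v.mean(),
                "se": se,
                "min": v.min(),
                "max": v.max(),
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, stage: str, **kwargs) -> Path:
    df.to_csv(path, **kwargs)
    logger.info("stage=%s wrote %s sha256=%s", stage, path.name, _sha256(path))
    return path


def _read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="locus_id")


def _load_inputs(config: RunConfig, out: Path):
    if config.sim is not None:
        ds = simulate_dataset(config.sim)
        ds.write(out)
        return ds.meta, ds.rad, ds.epirad, ds.telomeres
    meta = pd.read_csv(config.meta_path)
    rad = _read_counts(config.rad_path)
    epi = _read_counts(config.epirad_path)
    telo = pd.read_csv(config.telomere_path) if config.telomere_path else None
    return meta, rad, epi, telo


def _tissue_table(meta: pd.DataFrame, values: pd.Series, value_col: str) -> pd.DataFrame:
    samples = meta.drop_duplicates("sample_id")[
        ["sample_id", "individual_id", "sex", "age_group", "tissue", "body_size_mm"]
    ].set_index("sample_id")
    out = samples.join(values.rename(value_col)).reset_index()
    return out


def _fin_gonad_table(tidy: pd.DataFrame, value_col: str) -> pd.DataFrame:
    wide = tidy.pivot_table(
        index=["individual_id", "sex", "age_group"],
        columns="tissue",
        values=value_col,
    ).reset_index()
    wide = wide.rename(columns={"fin": "fin_value", "gonad": "gonad_value"})
    return wide.dropna(subset=["fin_value", "gonad_value"])


def _model_block(tidy: pd.DataFrame, value_col: str, include_body: bool, out: Path,
                 label: str) -> dict:
    """Tissue-level AGE/SEX selection plus the fin->gonad surrogate models."""
    block: dict = {}
    for tissue in ("fin", "gonad"):
        sub = tidy[tidy.tissue == tissue].rename(columns={value_col: "response"})
        cands = stats.tissue_model_candidates("response", include_body_size=include_body)
        table, fits = stats.select_model(cands, sub)
        _write(table, out / f"model_selection_{label}_{tissue}.csv", "models", index=False)
        best = fits[table.name.iloc[0]]
        addsex = fits["AGE+SEX"]
        _write(best.coef, out / f"coefficients_{label}_{tissue}.csv", "models")
        grid = sub[["age_group", "sex"]].drop_duplicates().sort_values(
            ["age_group", "sex"]).reset_index(drop=True)
        means = stats.estimated_means(addsex, grid)
        _write(means, out / f"estimated_means_{label}_{tissue}.csv", "models", index=False)
        block[tissue] = {
            "best_model": table.name.iloc[0],
            "selection": table.to_dict(orient="records"),
            "age_sex_f_tests": stats.term_f_tests(addsex).to_dict(orient="records"),
            "best_adj_r_squared": best.adj_r_squared,
        }
    fg = _fin_gonad_table(tidy, value_col)
    table, fits = stats.select_model(stats.fin_gonad_model_candidates("gonad_value"), fg)
    _write(table, out / f"model_selection_{label}_fin_gonad.csv", "models", index=False)
    best = fits[table.name.iloc[0]]
    _write(best.coef, out / f"coefficients_{label}_fin_gonad.csv", "models")
    addsex = fits["fin+SEX"]
    block["fin_gonad"] = {
        "best_model": table.name.iloc[0],
        "selection": table.to_dict(orient="records"),
        "slope": float(addsex.coef.loc["fin_value", "estimate"]),
        "slope_se": float(addsex.coef.loc["fin_value", "se"]),
        "male_offset": float(addsex.coef.loc["C(sex, Treatment('F'))[T.M]", "estimate"]),
        "male_offset_se": float(addsex.coef.loc["C(sex, Treatment('F'))[T.M]", "se"]),
        "adj_r_squared_fin_sex": addsex.adj_r_squared,
        "best_adj_r_squared": best.adj_r_squared,
    }
    return block


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "epiradkit_version": __version__,
            "seed": config.sim.seed if config.sim is not None else config.seed,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    # stage: inputs
    try:
        meta, rad, epi, telo = _load_inputs(config, out)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineError(f"stage=input: {e}") from e

    # stage: methylation calling
    try:
        rad_cpm = epirad.cpm_normalize(rad)
        filt = epirad.filter_loci(rad_cpm, threshold=config.cpm_threshold)
        _write(filt.report, out / "locus_filter_report.tsv", "filter", sep="\t")
        pd.Series(filt.retained, name="locus_id").to_frame().to_csv(
            out / "retained_loci.tsv", sep="\t", index=False
        )
        calls = epirad.call_methylation(epi, filt.retained, meta)
        _write(calls, out / "methylation_calls.tsv", "call", sep="\t",
               index_label="locus_id")
        props = epirad.methylation_proportion(calls)
        prop_tidy = _tissue_table(meta, props, "meth_pct")
        _write(prop_tidy, out / "methylation_proportions.csv", "call", index=False)
    except Exception as e:
        raise PipelineError(f"stage=methylation-calling: {e}") from e

    # stage: sensitivity of the retention threshold
    try:
        thresholds = sorted({config.cpm_threshold, *config.sensitivity_thresholds})
        sens = epirad.threshold_sensitivity(rad, epi, meta, thresholds=thresholds)
        _write(sens, out / "threshold_sensitivity.csv", "sensitivity",
               index_label="sample_id")
    except Exception as e:
        raise PipelineError(f"stage=sensitivity: {e}") from e

    # stage: summaries + t-tests
    try:
        summ = summarize_proportions(prop_tidy, "meth_pct", by=("tissue",))
        _write(summ, out / "proportion_summary.csv", "summary", index=False)
        fin = prop_tidy.loc[prop_tidy.tissue == "fin", "meth_pct"]
        gon = prop_tidy.loc[prop_tidy.tissue == "gonad", "meth_pct"]
        t, df, p = stats.welch_t_test(fin, gon)
        report["methylation"] = {
            "n_loci_input": int(rad.shape[0]),
            "n_retained_loci": int(len(filt)),
            "cpm_threshold": config.cpm_threshold,
            "summary": summ.to_dict(orient="records"),
            "fin_vs_gonad_t_test": {"t": t, "df": df, "p": p},
            "sensitivity_max_abs_delta": float(sens["max_abs_delta"].max()),
        }
    except Exception as e:
        raise PipelineError(f"stage=summaries: {e}") from e

    # stage: shared-status accounting + concordance
    try:
        universe, uniform = epirad.differential_loci(calls)
        samples = meta.drop_duplicates("sample_id")
        shared = []
        for (tissue, sex), grp in samples.groupby(["tissue", "sex"], sort=True):
            s = epirad.shared_status_counts(
                calls, grp.sample_id.tolist(), universe, label=f"{tissue}:{sex}"
            )
            shared.append(s.to_dict())
        per_ind, per_sex = epirad.fin_gonad_concordance(calls, meta, universe)
        _write(per_ind, out / "fin_gonad_concordance.csv", "shared", index=False)
        (out / "shared_status.json").write_text(json.dumps(shared, indent=2))
        report["methylation"].update(
            {
                "n_differential_loci": int(len(universe)),
                "n_uniform_loci": int(len(uniform)),
                "shared_status": shared,
                "concordance": {
                    "min_shared": int(per_ind.n_shared_methylated.min()),
                    "max_shared": int(per_ind.n_shared_methylated.max()),
                    "min_pct": float(per_ind.pct_shared_methylated.min()),
                    "max_pct": float(per_ind.pct_shared_methylated.max()),
                    "per_sex_intersection": per_sex,
                },
            }
        )
    except Exception as e:
        raise PipelineError(f"stage=shared-status: {e}") from e

    # stage: models (methylation)
    try:
        report["methylation"]["models"] = _model_block(
            prop_tidy, "meth_pct", include_body=False, out=out, label="meth"
        )
    except Exception as e:
        raise PipelineError(f"stage=methylation-models: {e}") from e

    # stage: telomeres
    if telo is not None:
        try:
            telo_summ = summarize_proportions(telo, "median_kb", by=("tissue",))
            _write(telo_summ, out / "telomere_summary.csv", "telomere", index=False)
            fin = telo.loc[telo.tissue == "fin", "median_kb"]
            gon = telo.loc[telo.tissue == "gonad", "median_kb"]
            t, df, p = stats.welch_t_test(fin, gon)
            tidy_t = telo.copy()
            if "body_size_mm" not in tidy_t.columns:
                body = meta.drop_duplicates("individual_id")[
                    ["individual_id", "body_size_mm"]
                ]
                tidy_t = tidy_t.merge(body, on="individual_id", how="left")
            report["telomeres"] = {
                "summary": telo_summ.to_dict(orient="records"),
                "fin_vs_gonad_t_test": {"t": t, "df": df, "p": p},
                "models": _model_block(
                    tidy_t, "median_kb", include_body=True, out=out, label="telo"
                ),
            }
        except Exception as e:
            raise PipelineError(f"stage=telomeres: {e}") from e

    # stage: ordination
    try:
        D = ordination.binary_distance(calls, universe, metric=config.mds_metric)
        mds = ordination.classical_mds(D, n_axes=config.mds_axes)
        coords = mds.coordinates.join(
            meta.drop_duplicates("sample_id")
            .set_index("sample_id")[["individual_id", "tissue", "sex", "age_group"]]
        )
        _write(coords, out / "mds_coordinates.csv", "ordination", index_label="sample_id")
        var = pd.DataFrame(
            {
                "axis": [f"MDS{i+1}" for i in range(mds.n_axes)],
                "percent_variance": mds.percent_variance,
            }
        )
        _write(var, out / "mds_variance.csv", "ordination", index=False)
        report["ordination"] = {
            "metric": config.mds_metric,
            "percent_variance": [float(v) for v in mds.percent_variance],
        }
    except Exception as e:
        raise PipelineError(f"stage=ordination: {e}") from e

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# epiradkit run report", ""]
    meth = report.get("methylation", {})
    if meth:
        lines += [
            "## Methylation",
            f"- retained loci: {meth['n_retained_loci']} of {meth['n_loci_input']} "
            f"(CPM >= {meth['cpm_threshold']} in all RAD libraries)",
            f"- differential loci: {meth.get('n_differential_loci', 'n/a')}",
        ]
        for row in meth.get("summary", []):
            se = row["se"]
            se_txt = f"{se:.2f}" if se == se else "n/a"
            lines.append(
                f"- {row['tissue']}: {row['mean']:.2f} +/- {se_txt}% "
                f"(range {row['min']:.2f}-{row['max']:.2f}, n={row['n']})"
            )
        tt = meth.get("fin_vs_gonad_t_test")
        if tt:
            lines.append(
                f"- fin vs gonad Welch t-test: t_{tt['df']:.1f} = {tt['t']:.2f}, "
                f"p = {tt['p']:.3g}"
            )
    telo = report.get("telomeres", {})
    if telo:
        lines += ["", "## Telomeres"]
        for row in telo.get("summary", []):
            se = row["se"]
            se_txt = f"{se:.2f}" if se == se else "n/a"
            lines.append(
                f"- {row['tissue']}: {row['mean']:.2f} +/- {se_txt} kb "
                f"(range {row['min']:.2f}-{row['max']:.2f}, n={row['n']})"
            )
        fg = telo.get("models", {}).get("fin_gonad", {})
        if fg:
            lines.append(
                f"- fin->gonad slope {fg['slope']:.2f} +/- {fg['slope_se']:.2f}, "
                f"male offset {fg['male_offset']:.2f} +/- {fg['male_offset_se']:.2f}, "
                f"adj R^2 = {fg['adj_r_squared_fin_sex']:.3f}"
            )
    ordn = report.get("ordination", {})
    if ordn:
        pv = ", ".join(f"{v:.1f}%" for v in ordn.get("percent_variance", []))
        lines += ["", "## Ordination", f"- axis variance: {pv}"]
    return "\n".join(lines) + "\n"
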