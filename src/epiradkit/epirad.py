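"""Presence/absence methylation inference from paired RAD/EpiRAD counts.

The comparison of a methylation-insensitive (MspI, "RAD") and a
methylation-sensitive (HpaII, "EpiRAD") library from the same DNA sample
turns restriction-site methylation into locus dropout: a fully methylated
CCGG locus yields no EpiRAD reads.  The inference here is deliberately
conservative — after CPM standardisation, loci well covered in *every* RAD
library are retained, and a retained locus is called methylated in a sample
iff its raw EpiRAD count is exactly zero.  Partially methylated loci keep
some reads and are therefore called unmethylated, so the called proportion
underestimates total methylation; this is a property of the assay, not a bug.

Array-facing estimators follow the scikit-learn convention (libraries as
rows, loci as columns) and compose in pipelines; the module-level functions
accept the field's loci x libraries DataFrames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

DEFAULT_CPM_THRESHOLD = 15.0
SENSITIVITY_THRESHOLDS = (7.0, 15.0, 21.0)


class CPMNormalizer(TransformerMixin, BaseEstimator):
    """Scale each library (row) to counts per million.

    CPM[i, j] = count[i, j] / library_size[i] * 1e6, with the library size
    taken as the row sum over reference loci.  Stateless apart from recording
    the library sizes seen in :meth:`fit`.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype="numeric", ensure_min_features=1)
        self.n_features_in_ = X.shape[1]
        self.library_size_ = X.sum(axis=1)
        return self

    def transform(self, X):
        check_is_fitted(self, "library_size_")
        X = check_array(X, dtype="numeric")
        sizes = X.sum(axis=1)
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        zero = np.flatnonzero(sizes == 0)
        if zero.size:
            raise ValueError(f"library rows {zero.tolist()} have zero total reads")
        return X / sizes[:, None] * 1e6


class MinCPMLocusFilter(SelectorMixin, BaseEstimator):
    """Retain loci whose CPM meets a threshold in every (RAD) library.

    Fit on a CPM matrix of the methylation-insensitive libraries only; the
    retained support is then applied to any matrix with the same loci.
    """

    def __init__(self, threshold: float = DEFAULT_CPM_THRESHOLD):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = check_array(X, dtype="numeric")
        self.n_features_in_ = X.shape[1]
        self.min_cpm_ = X.min(axis=0)
        self.support_ = self.min_cpm_ >= self.threshold
        if not self.support_.any():
            warnings.warn("no locus passes the CPM retention threshold", stacklevel=2)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class ZeroReadCaller(TransformerMixin, BaseEstimator):
    """Binary methylation calls from raw EpiRAD counts: 1 iff count == 0.

    The rule depends only on zeros, so it is invariant to any positive
    rescaling of a library's counts.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype="numeric")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X, dtype="numeric")
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        return (X == 0).astype(np.int8)


# ---------------------------------------------------------------------------
# DataFrame surface (loci x libraries, as written by the simulator / ipyrad
# count extraction)


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million standardisation of a loci x libraries matrix.

    Raises ``ValueError`` naming any library with zero total reads.
    """
    sizes = counts.sum(axis=0)
    empty = sizes.index[sizes == 0].tolist()
    if empty:
        raise ValueError(f"libraries with zero total reads: {empty}")
    norm = CPMNormalizer().fit(counts.T.to_numpy(dtype=float))
    out = norm.transform(counts.T.to_numpy(dtype=float)).T
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


@dataclass
class FilterResult:
    """Retained loci plus the per-locus pass/fail report."""

    retained: pd.Index
    threshold: float
    report: pd.DataFrame  # columns: min_cpm, retained

    def __len__(self):
        return len(self.retained)


def filter_loci(cpm_rad: pd.DataFrame, threshold: float = DEFAULT_CPM_THRESHOLD) -> FilterResult:
    """Retain loci with CPM >= ``threshold`` in every RAD library.

    ``cpm_rad`` must contain only methylation-insensitive libraries.  An empty
    retained set is returned with a warning rather than raising.
    """
    sel = MinCPMLocusFilter(threshold=threshold).fit(cpm_rad.T.to_numpy(dtype=float))
    mask = sel.get_support()
    report = pd.DataFrame(
        {"min_cpm": sel.min_cpm_, "retained": mask}, index=cpm_rad.index
    )
    return FilterResult(cpm_rad.index[mask], float(threshold), report)


def pair_libraries(meta: pd.DataFrame) -> pd.DataFrame:
    """Map each EpiRAD library to its sample via the (individual, tissue) key.

    Raises ``ValueError`` for any EpiRAD library without a RAD partner.
    """
    rad = meta[meta.library_type == "RAD"]
    epi = meta[meta.library_type == "EpiRAD"]
    rad_keys = set(zip(rad.individual_id, rad.tissue))
    unpaired = [
        lib for lib, ind, tis in zip(epi.library_id, epi.individual_id, epi.tissue)
        if (ind, tis) not in rad_keys
    ]
    if unpaired:
        raise ValueError(f"EpiRAD libraries without a paired RAD library: {unpaired}")
    return epi[["library_id", "sample_id", "individual_id", "tissue"]].reset_index(drop=True)


def call_methylation(
    counts_epirad: pd.DataFrame,
    retained: pd.Index | list,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Binary call matrix over retained loci: 1 iff the raw EpiRAD count is 0.

    When ``meta`` is given the EpiRAD columns are renamed to sample ids after
    verifying RAD/EpiRAD pairing by (individual, tissue); unpaired libraries
    raise.  Loci listed in ``retained`` but absent from the matrix count as 0
    reads (methylated) per count-matrix semantics.
    """
    retained = pd.Index(retained)
    sub = counts_epirad.reindex(retained, fill_value=0)
    calls = pd.DataFrame(
        ZeroReadCaller().fit_transform(sub.T.to_numpy(dtype=float)).T,
        index=retained,
        columns=sub.columns,
    )
    if meta is not None:
        pairing = pair_libraries(meta)
        mapping = dict(zip(pairing.library_id, pairing.sample_id))
        missing = [c for c in calls.columns if c not in mapping]
        if missing:
            raise ValueError(f"EpiRAD libraries absent from metadata: {missing}")
        calls = calls.rename(columns=mapping)
    return calls


def methylation_proportion(calls: pd.DataFrame) -> pd.Series:
    """Per-sample percentage of retained loci called methylated."""
    if calls.shape[0] == 0:
        raise ValueError("no retained loci: methylation proportion undefined")
    return calls.mean(axis=0) * 100.0


def differential_loci(calls: pd.DataFrame):
    """Split retained loci into differential and uniform sets.

    Returns ``(differential_ids, uniform_states)`` where ``uniform_states`` is
    a Series (locus -> 0/1) over the loci whose call is identical in every
    sample.  Differential loci are the complement.
    """
    if calls.shape[1] < 2:
        raise ValueError("need at least 2 samples to assess differential status")
    arr = calls.to_numpy()
    uniform_mask = (arr == arr[:, [0]]).all(axis=1)
    uniform = pd.Series(arr[uniform_mask, 0], index=calls.index[uniform_mask], dtype=int)
    return calls.index[~uniform_mask], uniform


@dataclass
class SharedStatusSummary:
    """Counts of universe loci with a uniform call across a sample group."""

    group: str
    n_samples: int
    n_differential_loci: int
    n_uniform_unmethylated: int
    n_uniform_methylated: int

    @property
    def pct_uniform_unmethylated(self) -> float:
        return 100.0 * self.n_uniform_unmethylated / self.n_differential_loci

    @property
    def pct_uniform_methylated(self) -> float:
        return 100.0 * self.n_uniform_methylated / self.n_differential_loci

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_samples": self.n_samples,
            "n_differential_loci": self.n_differential_loci,
            "n_uniform_unmethylated": self.n_uniform_unmethylated,
            "n_uniform_methylated": self.n_uniform_methylated,
            "pct_uniform_unmethylated": round(self.pct_uniform_unmethylated, 2),
            "pct_uniform_methylated": round(self.pct_uniform_methylated, 2),
        }


def shared_status_counts(
    calls: pd.DataFrame, group: list, universe: pd.Index | list, label: str = ""
) -> SharedStatusSummary:
    """Uniformly (un)methylated counts within a sample group, over the
    differential-locus universe, with percentages of that universe."""
    group = list(group)
    if not group:
        raise ValueError("group must be non-empty")
    unknown = [g for g in group if g not in calls.columns]
    if unknown:
        raise ValueError(f"group references unknown samples: {unknown}")
    universe = pd.Index(universe)
    sub = calls.loc[universe, group].to_numpy()
    return SharedStatusSummary(
        group=label or ",".join(group),
        n_samples=len(group),
        n_differential_loci=len(universe),
        n_uniform_unmethylated=int((sub == 0).all(axis=1).sum()),
        n_uniform_methylated=int((sub == 1).all(axis=1).sum()),
    )


def fin_gonad_concordance(
    calls: pd.DataFrame, meta: pd.DataFrame, universe: pd.Index | list
):
    """Per-individual count (and %) of universe loci methylated in both tissues.

    Returns ``(per_individual, per_sex_intersection)``: a DataFrame with one
    row per individual (individuals missing a tissue are skipped with a
    warning) and a dict sex -> number of universe loci methylated in both
    tissues of *every* individual of that sex.
    """
    universe = pd.Index(universe)
    samples = meta.drop_duplicates("sample_id")[
        ["sample_id", "individual_id", "sex", "tissue"]
    ]
    rows = []
    both_by_sex: dict = {}
    for ind, grp in samples.groupby("individual_id", sort=True):
        tissues = dict(zip(grp.tissue, grp.sample_id))
        if "fin" not in tissues or "gonad" not in tissues or not {
            tissues.get("fin"), tissues.get("gonad")
        } <= set(calls.columns):
            warnings.warn(f"individual {ind}: missing fin or gonad calls, skipped",
                          stacklevel=2)
            continue
        fin = calls.loc[universe, tissues["fin"]].to_numpy()
        gonad = calls.loc[universe, tissues["gonad"]].to_numpy()
        both = (fin == 1) & (gonad == 1)
        sex = grp.sex.iloc[0]
        rows.append(
            {
                "individual_id": ind,
                "sex": sex,
                "n_shared_methylated": int(both.sum()),
                "pct_shared_methylated": 100.0 * both.sum() / len(universe),
            }
        )
        both_by_sex[sex] = both_by_sex.get(sex, np.ones(len(universe), bool)) & both
    per_ind = pd.DataFrame(rows)
    per_sex = {s: int(m.sum()) for s, m in both_by_sex.items()}
    return per_ind, per_sex


def threshold_sensitivity(
    counts_rad: pd.DataFrame,
    counts_epirad: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    thresholds=SENSITIVITY_THRESHOLDS,
) -> pd.DataFrame:
    """Per-sample called proportions at each retention threshold.

    One column per threshold plus ``max_abs_delta``, the largest pairwise
    difference per sample — the robustness check for the retention cut-off.
    """
    cpm_rad = cpm_normalize(counts_rad)
    cols = {}
    for thr in thresholds:
        res = filter_loci(cpm_rad, threshold=thr)
        calls = call_methylation(counts_epirad, res.retained, meta)
        cols[f"pct_at_{thr:g}"] = methylation_proportion(calls)
    out = pd.DataFrame(cols)
    vals = out.to_numpy()
    out["max_abs_delta"] = vals.max(axis=1) - vals.min(axis=1)
    return out
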