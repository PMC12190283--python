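"""Group-level statistics on entropy grids and classification accuracy.

The battery comprises:

* Welch two-tailed t-tests per (scale, channel) cell with
  Benjamini-Hochberg FDR correction across the whole grid, plus
  Cohen's d effect sizes, comparing the AD and HS groups on
  subject-level entropy (each subject's epochs averaged first, so
  epochs are not treated as independent subjects);
* a two-between (group, dataset) one-within (scale) mixed-design ANOVA
  on channel-averaged entropy, computed in its two error strata with
  type-III sums of squares and Greenhouse-Geisser correction of the
  within-factor p-values;
* paired one-tailed t-tests asking whether an amplitude condition
  improves per-subject test accuracy over the reference condition;
* averaged inter-channel Pearson correlation matrices per condition
  (the transforms are affine per channel, so these should coincide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .entropy import MFEMatrix
from .recording import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "subject_mean_mfe",
    "channel_mean_long",
    "ttest_grid_fdr",
    "cohens_d",
    "mixed_anova",
    "accuracy_condition_test",
    "correlation_preservation",
]


def subject_mean_mfe(matrices: list[MFEMatrix]):
    """Average each subject's epochs: meta frame + subj x channel x scale."""
    meta = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in matrices],
            "group": [m.group for m in matrices],
            "dataset_id": [m.dataset_id for m in matrices],
        }
    )
    values = np.stack([m.values.mean(axis=0) for m in matrices])
    return meta, values


def channel_mean_long(matrices: list[MFEMatrix]) -> pd.DataFrame:
    """Channel- and epoch-averaged entropy, long format (one row per
    subject x scale) — the mixed-ANOVA input."""
    meta, values = subject_mean_mfe(matrices)
    scales = matrices[0].params.scales
    per_scale = values.mean(axis=1)  # subj x scale
    rows = []
    for i, m in meta.iterrows():
        for s_idx, tau in enumerate(scales):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "group": m.group,
                    "dataset_id": m.dataset_id,
                    "scale": int(tau),
                    "value": per_scale[i, s_idx],
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ t-test grid

@dataclass
class GridTestResult:
    """Per-cell p-values (raw and FDR-adjusted), mask and effect sizes.

    Arrays are channel x scale; NaN marks cells where both groups were
    constant (test undefined).
    """

    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    d: np.ndarray
    alpha: float = 0.05


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d = (mean(a) - mean(b)) / pooled SD (N-1 weighted)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        logger.warning("cohens_d: zero pooled SD; returning NaN")
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def ttest_grid_fdr(
    values_a: np.ndarray,
    values_b: np.ndarray,
    alpha: float = 0.05,
) -> GridTestResult:
    """Welch t-test per (channel, scale) cell, BH-corrected over the grid.

    ``values_a``/``values_b`` are subj x channel x scale arrays of
    per-subject entropy for the two groups.
    """
    if values_a.shape[0] < 2 or values_b.shape[0] < 2:
        raise ValueError("need at least two subjects per group")
    res = sps.ttest_ind(values_a, values_b, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    both_const = (values_a.std(axis=0) == 0) & (values_b.std(axis=0) == 0)
    if both_const.any():
        logger.warning("%d grid cells constant in both groups", both_const.sum())
        p[both_const] = np.nan
    flat = p.ravel()
    ok = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = multipletests(flat[ok], alpha=alpha, method="fdr_bh")[1]
    p_adj = adj.reshape(p.shape)
    d = np.full(p.shape, np.nan)
    for c in range(p.shape[0]):
        for s in range(p.shape[1]):
            if not both_const[c, s]:
                d[c, s] = cohens_d(values_a[:, c, s], values_b[:, c, s])
    return GridTestResult(
        p_raw=p, p_adj=p_adj, significant=(p_adj < alpha), d=d, alpha=alpha
    )


# ------------------------------------------------------------ mixed ANOVA

def _gg_epsilon(wide: np.ndarray, cell_codes: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-cell covariance.

    ``wide`` is subjects x scales; ``cell_codes`` labels each subject's
    between-cell.
    """
    p = wide.shape[1]
    pooled = np.zeros((p, p))
    dof = 0
    for cell in np.unique(cell_codes):
        block = wide[cell_codes == cell]
        if len(block) < 2:
            continue
        centered = block - block.mean(axis=0)
        pooled += centered.T @ centered
        dof += len(block) - 1
    S = pooled / max(dof, 1)
    C = np.eye(p) - np.full((p, p), 1.0 / p)
    Sd = C @ S @ C
    num = np.trace(Sd) ** 2
    den = (p - 1) * np.trace(Sd @ Sd)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (p - 1))))


def mixed_anova(long: pd.DataFrame) -> pd.DataFrame:
    """Two-between, one-within mixed-design ANOVA.

    ``long`` has one row per subject x scale with columns
    ``subject_id``, ``group``, ``dataset_id``, ``scale``, ``value``;
    every subject must contribute every scale level, and every
    (group, dataset) cell must be non-empty.

    Between effects (Group, Dataset, Group x Dataset) are tested on
    subject means against the between-subject error; within effects
    (Scale and its interactions) in a model with subject intercepts
    absorbed, against the scale-by-subject residual, with
    Greenhouse-Geisser-corrected p-values alongside the uncorrected
    ones. Type-III sums of squares, sum-to-zero coding.
    """
    df = long.copy()
    scales = np.sort(df["scale"].unique())
    n_scales = len(scales)
    counts = df.groupby("subject_id")["scale"].nunique()
    if (counts != n_scales).any():
        raise ValueError("every subject must have every scale level")
    cells = df.drop_duplicates("subject_id").groupby(
        ["group", "dataset_id"], observed=True
    ).size()
    if (cells < 2).any() or len(cells) != (
        df["group"].nunique() * df["dataset_id"].nunique()
    ):
        raise ValueError("empty or singleton (group, dataset) cells")

    # ---- between stratum: subject means
    subj = (
        df.groupby(["subject_id", "group", "dataset_id"], as_index=False)["value"]
        .mean()
    )
    with_dataset = df["dataset_id"].nunique() > 1

    # sum-to-zero contrasts
    g_code = np.where(
        subj["group"] == sorted(subj["group"].unique())[0], 1.0, -1.0
    )
    if with_dataset:
        d_code = np.where(
            subj["dataset_id"] == sorted(subj["dataset_id"].unique())[0], 1.0, -1.0
        )

    # ---- between stratum: type-III drop-term tests on subject means
    y_b = subj["value"].to_numpy()
    blocks_b = {"Intercept": np.ones((len(subj), 1)), "Group": g_code[:, None]}
    if with_dataset:
        blocks_b["Dataset"] = d_code[:, None]
        blocks_b["Group x Dataset"] = (g_code * d_code)[:, None]
    between = _type3_tests(y_b, blocks_b, skip=("Intercept",))

    # ---- within stratum: subject dummies absorb all between variation
    df = df.sort_values(["subject_id", "scale"], kind="stable")
    sub_ids = subj["subject_id"].to_numpy()
    sub_index = {s: i for i, s in enumerate(sub_ids)}
    rows_sub = df["subject_id"].map(sub_index).to_numpy()
    n_rows = len(df)
    D = np.zeros((n_rows, len(sub_ids)))
    D[np.arange(n_rows), rows_sub] = 1.0
    # sum-coded scale contrasts per row
    S_levels = np.vstack([np.eye(n_scales - 1), -np.ones(n_scales - 1)])
    scale_idx = df["scale"].map({t: i for i, t in enumerate(scales)}).to_numpy()
    S = S_levels[scale_idx]
    g_rows = g_code[rows_sub][:, None]
    blocks_w = {"Subject": D, "Scale": S, "Scale x Group": S * g_rows}
    if with_dataset:
        d_rows = d_code[rows_sub][:, None]
        blocks_w["Scale x Dataset"] = S * d_rows
        blocks_w["Scale x Group x Dataset"] = S * g_rows * d_rows
    within = _type3_tests(df["value"].to_numpy(), blocks_w, skip=("Subject",))

    wide = (
        df.pivot_table(index="subject_id", columns="scale", values="value")
        .loc[sub_ids]
        .to_numpy()
    )
    cell_codes = (subj["group"] + "/" + subj["dataset_id"]).to_numpy()
    eps = _gg_epsilon(wide, cell_codes)

    order = ["Scale", "Group"]
    if with_dataset:
        order.append("Dataset")
    order.append("Scale x Group")
    if with_dataset:
        order += ["Group x Dataset", "Scale x Dataset", "Scale x Group x Dataset"]
    rows = []
    for effect in order:
        src = within if effect.startswith("Scale") else between
        f, df1, df2 = src[effect]
        entry = {
            "effect": effect,
            "F": f,
            "df1": df1,
            "df2": df2,
            "p": float(sps.f.sf(f, df1, df2)),
            "eps": np.nan,
            "p_gg": np.nan,
        }
        if effect.startswith("Scale"):
            entry["eps"] = eps
            entry["p_gg"] = float(sps.f.sf(f, df1 * eps, df2 * eps))
        rows.append(entry)
    return pd.DataFrame(rows).set_index("effect")


def _type3_tests(y: np.ndarray, blocks: dict, skip=()) -> dict:
    """Type-III F tests by refitting with each column block removed.

    ``blocks`` maps effect name -> design-matrix columns; the error term
    is the full-model residual. Returns name -> (F, df1, df2).
    """
    names = list(blocks)
    X_full = np.hstack([blocks[n] for n in names])
    rank_full = np.linalg.matrix_rank(X_full)
    beta, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_full = float(((y - X_full @ beta) ** 2).sum())
    df_err = len(y) - rank_full
    ms_err = rss_full / df_err if df_err > 0 else np.nan
    out = {}
    for name in names:
        if name in skip:
            continue
        X_red = np.hstack([blocks[n] for n in names if n != name])
        beta_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
        rss_red = float(((y - X_red @ beta_r) ** 2).sum())
        df1 = rank_full - np.linalg.matrix_rank(X_red)
        f = ((rss_red - rss_full) / df1) / ms_err if df1 > 0 else np.nan
        out[name] = (float(f), float(df1), float(df_err))
    return out


# ------------------------------------------------- accuracy comparisons

def accuracy_condition_test(
    reports_ref: dict[str, float], reports_cond: dict[str, float]
) -> float:
    """Paired one-tailed t-test: condition accuracy > reference accuracy.

    Both arguments map subject id -> accuracy and must cover the same
    test subjects. A degenerate zero-variance difference returns p = 0,
    0.5 or 1 by the sign of the common difference, with a log entry.
    """
    if set(reports_ref) != set(reports_cond):
        raise ValueError("accuracy comparisons must pair the same subjects")
    subjects = sorted(reports_ref)
    ref = np.array([reports_ref[s] for s in subjects])
    cond = np.array([reports_cond[s] for s in subjects])
    diff = cond - ref
    if np.allclose(diff.std(ddof=1), 0):
        logger.warning("accuracy_condition_test: zero-variance differences")
        if diff.mean() > 0:
            return 0.0
        return 0.5 if diff.mean() == 0 else 1.0
    return float(sps.ttest_rel(cond, ref, alternative="greater").pvalue)


# --------------------------------------------- correlation preservation

def correlation_preservation(
    cohort: list[Recording], conditions: list[str]
) -> dict[str, np.ndarray]:
    """Subject-averaged channel x channel Pearson matrices per condition.

    ``cohort`` should already be preprocessed; transforms are fitted and
    applied per subject inside. Constant channels yield NaN entries with
    a log message.
    """
    from .transforms import TransformSpec, apply_condition

    out = {}
    for cond in conditions:
        mats = []
        for rec in cohort:
            transformed, _ = apply_condition(rec, TransformSpec(cond))
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(transformed.data)
            if np.isnan(corr).any():
                logger.warning(
                    "constant channel in %s under %s", rec.subject_id, cond
                )
            mats.append(corr)
        out[cond] = np.mean(mats, axis=0)
    return out
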