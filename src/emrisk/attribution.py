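"""Occlusion attribution and the relative-contribution (RC) statistic.

A feature's contribution (FC) to one patient is the summed drop in predicted
risk when each occurrence of the feature in the lookback window is masked to
padding, one occurrence at a time.  Per patient the FC vector is normalized
by the total absolute contribution of all features.  The RC of a feature is
the ratio of its mean normalized FC among event patients to that among
non-event patients; its sampling variance on the log scale is

    Var ln RC = (sd_e / mean_e)^2 / n_e + (sd_c / mean_c)^2 / n_c

with sample standard deviations, giving the log-normal 95% interval
``exp(ln RC +/- 1.96 sqrt(Var))`` and a two-sided z-test p-value.  RC values
and interval bounds are finally rescaled so that the ubiquitous anchor
diagnosis (the AD code, carried by every patient) has RC exactly 1.

A protective feature has negative FC in both groups (masking it raises the
predicted risk); the ratio of two negative means is positive and RC < 1 then
means the feature moves predictions more strongly for non-event patients.
RC is undefined — the row is excluded with a reason — when the group means
have opposite signs or either is zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContributionMatrix",
    "occlusion_contribution",
    "contribution_matrix",
    "normalize_fc_v15",
    "relative_contribution",
    "variance_ln_rc",
    "confidence_interval",
    "p_value",
    "adjust_pvalues",
    "rc_table",
    "scale_to_anchor",
    "report_significant",
]

Z95 = 1.959963984540054  # Phi^-1(0.975)


# ---------------------------------------------------------------------------
# occlusion

def _variants(seq: list[list[int]], token: int):
    """Copies of ``seq`` with one occurrence of ``token`` masked to padding."""
    out = []
    for t, visit in enumerate(seq):
        for j, tok in enumerate(visit):
            if tok == token:
                var = [list(v) for v in seq]
                del var[t][j]
                out.append(var)
    return out


def occlusion_contribution(model, seq: list[list[int]], token: int) -> float:
    """Raw FC of one token for one packed sample: sum over occurrences of
    risk(original) - risk(occurrence masked)."""
    variants = _variants(seq, token)
    if not variants:
        return 0.0
    probs = model.predict_proba([seq] + variants)[:, 1]
    return float(np.sum(probs[0] - probs[1:]))


@dataclass
class ContributionMatrix:
    """Per-sample, per-feature contributions from occlusion.

    ``raw`` holds pre-normalization FC, ``normalized`` the per-row v1.5
    normalization, ``occurs`` the occurrence indicator used to restrict group
    means to samples actually carrying the feature, and ``labels`` the event
    indicator per row.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    occurs: pd.DataFrame
    labels: np.ndarray

    @property
    def features(self) -> list[str]:
        return list(self.raw.columns)

    def prevalence(self) -> pd.Series:
        """Fraction of samples carrying each feature."""
        return self.occurs.mean(axis=0)


def normalize_fc_v15(raw: np.ndarray) -> np.ndarray:
    """Per-patient normalization: FC_f / sum_g |FC_g| (all-zero rows stay zero)."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite feature contributions")
    denom = np.abs(raw).sum()
    if denom == 0.0:
        warnings.warn("all-zero contribution vector; normalization skipped")
        return raw.copy()
    return raw / denom


def contribution_matrix(model, seqs, labels, vocab) -> ContributionMatrix:
    """Occlude every token occurrence of every sample (batched per sample)."""
    codes = [vocab.code_of[t] for t in sorted(vocab.code_of)]
    token_pos = {t: i for i, t in enumerate(sorted(vocab.code_of))}
    n, m = len(seqs), len(codes)
    raw = np.zeros((n, m))
    occurs = np.zeros((n, m), dtype=bool)
    for r, seq in enumerate(seqs):
        occ: list[tuple[int, int, int]] = []  # (t, j, token)
        for t, visit in enumerate(seq):
            for j, tok in enumerate(visit):
                occ.append((t, j, tok))
        if not occ:
            continue
        batch = [seq]
        for t, j, _ in occ:
            var = [list(v) for v in seq]
            del var[t][j]
            batch.append(var)
        probs = model.predict_proba(batch)[:, 1]
        deltas = probs[0] - probs[1:]
        for (t, j, tok), d in zip(occ, deltas):
            k = token_pos[tok]
            raw[r, k] += d
            occurs[r, k] = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalized = np.array([normalize_fc_v15(row) for row in raw])
    idx = pd.RangeIndex(n)
    return ContributionMatrix(
        raw=pd.DataFrame(raw, index=idx, columns=codes),
        normalized=pd.DataFrame(normalized, index=idx, columns=codes),
        occurs=pd.DataFrame(occurs, index=idx, columns=codes),
        labels=np.asarray(labels, dtype=int),
    )


def crossfit_contribution_matrix(make_model, seqs, labels, patient_ids, vocab,
                                 n_folds: int = 2, val_fraction: float = 0.15,
                                 seed: int = 0) -> ContributionMatrix:
    """Cross-fitted occlusion contributions.

    Contributions computed with a model on its own training samples are
    anticonservative: the model amplifies chance case/control prevalence
    imbalances it overfitted, inflating the type-I error of the RC z-test.
    Cross-fitting restores calibration at full sample size: patients are
    partitioned into ``n_folds`` groups and each group's contributions come
    from a model trained on the remaining groups (with an internal
    patient-level validation split for early stopping).
    """
    labels = np.asarray(labels, dtype=int)
    pids = np.asarray(patient_ids)
    rng = np.random.default_rng(seed)
    unique = np.unique(pids)
    rng.shuffle(unique)
    fold_of = {pid: i % n_folds for i, pid in enumerate(unique)}
    assign = np.array([fold_of[p] for p in pids])
    parts: list[ContributionMatrix] = []
    order: list[np.ndarray] = []
    for f in range(n_folds):
        hold = np.flatnonzero(assign == f)
        fit_idx = np.flatnonzero(assign != f)
        fit_pids = np.unique(pids[fit_idx])
        rng.shuffle(fit_pids)
        n_val = max(1, int(round(val_fraction * len(fit_pids))))
        val_set = set(fit_pids[:n_val])
        tr = [i for i in fit_idx if pids[i] not in val_set]
        va = [i for i in fit_idx if pids[i] in val_set]
        model = make_model(seed + 1 + f)
        model.fit([seqs[i] for i in tr], labels[tr],
                  X_val=[seqs[i] for i in va], y_val=labels[va])
        parts.append(contribution_matrix(
            model, [seqs[i] for i in hold], labels[hold], vocab))
        order.append(hold)
    perm = np.argsort(np.concatenate(order))
    raw = pd.concat([p.raw for p in parts], ignore_index=True).iloc[perm].reset_index(drop=True)
    normd = pd.concat([p.normalized for p in parts], ignore_index=True).iloc[perm].reset_index(drop=True)
    occurs = pd.concat([p.occurs for p in parts], ignore_index=True).iloc[perm].reset_index(drop=True)
    return ContributionMatrix(raw, normd, occurs, labels)


# ---------------------------------------------------------------------------
# the RC statistic

def relative_contribution(fc_event, fc_nonevent) -> float | None:
    """Ratio of arithmetic mean FC, event over non-event patients.

    Returns None (excluded) when the means have opposite signs or either is
    zero, in which case ln RC is undefined.
    """
    fc_event = np.asarray(fc_event, dtype=float)
    fc_nonevent = np.asarray(fc_nonevent, dtype=float)
    if fc_event.size == 0 or fc_nonevent.size == 0:
        raise ValueError("both groups must be non-empty")
    me, mc = fc_event.mean(), fc_nonevent.mean()
    if me == 0.0 or mc == 0.0 or (me > 0) != (mc > 0):
        return None
    return float(me / mc)


def variance_ln_rc(fc_event, fc_nonevent) -> float:
    """Delta-method variance of ln RC from the two coefficient-of-variation terms."""
    fc_event = np.asarray(fc_event, dtype=float)
    fc_nonevent = np.asarray(fc_nonevent, dtype=float)
    if fc_event.size < 2 or fc_nonevent.size < 2:
        raise ValueError("need >= 2 values per group")
    me, mc = fc_event.mean(), fc_nonevent.mean()
    if me == 0.0 or mc == 0.0:
        raise ValueError("zero group mean")
    se = fc_event.std(ddof=1)
    sc = fc_nonevent.std(ddof=1)
    return float((se / me) ** 2 / fc_event.size + (sc / mc) ** 2 / fc_nonevent.size)


def confidence_interval(rc: float, var_ln_rc: float) -> tuple[float, float]:
    """Log-normal 95% CI: exp(ln RC -/+ 1.96 sqrt(Var)); geometric mean of the
    bounds equals RC exactly."""
    if rc <= 0:
        raise ValueError("RC must be positive")
    if var_ln_rc < 0:
        raise ValueError("variance must be non-negative")
    half = Z95 * math.sqrt(var_ln_rc)
    return math.exp(math.log(rc) - half), math.exp(math.log(rc) + half)


def p_value(rc: float, var_ln_rc: float) -> float:
    """Two-sided z-test of ln RC = 0 using the same variance as the CI."""
    if rc <= 0:
        raise ValueError("RC must be positive")
    if var_ln_rc == 0.0:
        if rc == 1.0:
            return 1.0
        warnings.warn("zero variance with RC != 1; p set to 0")
        return 0.0
    z = abs(math.log(rc)) / math.sqrt(var_ln_rc)
    return float(2.0 * norm.sf(z))


def adjust_pvalues(pvals, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-testing adjustment; q >= p elementwise."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(pvals) == 0:
        return pvals.copy()
    key = {"bonferroni": "bonferroni",
           "benjamini_hochberg": "fdr_bh", "bh": "fdr_bh"}[method]
    return multipletests(pvals, method=key)[1]


def _feature_type(code: str) -> str:
    return code.split(":", 1)[0] if ":" in code else "DX"


def rc_table(cm: ContributionMatrix, method: str = "benjamini_hochberg",
             min_group: int = 2) -> pd.DataFrame:
    """One RC row per feature, with group means over all event / non-event
    samples (a patient without the feature contributes FC = 0, so RC carries
    the exposure-prevalence contrast as well as the per-carrier contribution).

    Columns mirror the report layout: feature, rc, ci_low, ci_high,
    variance_ln_rc, p, q, group sizes and means, and an exclusion flag for
    features whose RC or variance is undefined.
    """
    y = cm.labels.astype(bool)
    rows = []
    for code in cm.features:
        fe = cm.normalized.loc[y, code].to_numpy()
        fc = cm.normalized.loc[~y, code].to_numpy()
        row = dict(feature=code, feature_type=_feature_type(code),
                   n_event=len(fe), n_nonevent=len(fc),
                   mean_fc_event=np.nan, mean_fc_nonevent=np.nan,
                   rc=np.nan, ci_low=np.nan, ci_high=np.nan,
                   variance_ln_rc=np.nan, p=np.nan, q=np.nan,
                   excluded=False, exclude_reason="")
        if len(fe) < min_group or len(fc) < min_group:
            row.update(excluded=True, exclude_reason="too_few_patients")
            rows.append(row)
            continue
        row.update(mean_fc_event=fe.mean(), mean_fc_nonevent=fc.mean())
        rc = relative_contribution(fe, fc)
        if rc is None:
            row.update(excluded=True, exclude_reason="sign_mismatch")
            rows.append(row)
            continue
        var = variance_ln_rc(fe, fc)
        lo, hi = confidence_interval(rc, var)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = p_value(rc, var)
        row.update(rc=rc, ci_low=lo, ci_high=hi, variance_ln_rc=var, p=p)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("feature")
    ok = ~table["excluded"]
    if ok.any():
        table.loc[ok, "q"] = adjust_pvalues(table.loc[ok, "p"].to_numpy(), method)
    return table


def scale_to_anchor(table: pd.DataFrame, anchor_feature: str,
                    method: str = "benjamini_hochberg",
                    recompute_significance: bool = False) -> pd.DataFrame:
    """Rescale rc/ci so the anchor feature's RC is exactly 1.

    The anchor (the AD diagnosis, present in every patient) calibrates the RC
    scale: per-patient normalization makes every feature's share depend on the
    total contribution budget, and the anchor's drift from 1 measures that
    bias.  By default p and q keep their values from the unscaled ratios (the
    direct test of "contributes more to cases than controls"); with
    ``recompute_significance`` the z-test and q are recomputed against the
    scaled null RC = 1, treating the anchor as a fixed calibration constant.
    """
    if anchor_feature not in table.index:
        raise ValueError(f"anchor feature {anchor_feature!r} not in table")
    arow = table.loc[anchor_feature]
    if bool(arow["excluded"]) or not np.isfinite(arow["rc"]):
        raise ValueError(f"anchor feature {anchor_feature!r} has undefined RC")
    factor = 1.0 / float(arow["rc"])
    out = table.copy()
    for col in ("rc", "ci_low", "ci_high"):
        out[col] = out[col] * factor
    out.loc[anchor_feature, "rc"] = 1.0  # exact despite float rounding
    if recompute_significance:
        ok = ~out["excluded"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.loc[ok, "p"] = [
                p_value(rc, var) for rc, var in
                zip(out.loc[ok, "rc"], out.loc[ok, "variance_ln_rc"])]
        if ok.any():
            out.loc[ok, "q"] = adjust_pvalues(out.loc[ok, "p"].to_numpy(), method)
    return out


def report_significant(table: pd.DataFrame, prevalence: pd.Series,
                       q_threshold: float = 0.05,
                       dx_prevalence_min: float = 0.10) -> pd.DataFrame:
    """Reportable rows: q below threshold; diagnoses additionally must appear
    in more than ``dx_prevalence_min`` of the population.  Sorted by feature
    type then increasing RC."""
    t = table[~table["excluded"] & (table["q"] < q_threshold)].copy()
    t["prevalence"] = prevalence.reindex(t.index)
    is_dx = t["feature_type"] == "DX"
    t = t[~is_dx | (t["prevalence"] > dx_prevalence_min)]
    return t.sort_values(["feature_type", "rc"])
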