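"""Mixed-effects characterization of cancer ASM.

Three analyses: (1) estimation of the average low/high-allele methylation
configuration at cancer-only ASM loci in cancer vs lineage-matched normal
cell types (linear mixed model with random intercept and slope per
locus), with LOM/GOM classification of the estimated configurations;
(2) enrichment of cancer-only ASM CpGs in baseline methylation classes of
the normal samples; (3) a multivariate mixed model of allelic methylation
difference on allelic binding-affinity difference with ASM-class
interaction, random intercept + slope per motif, and per-class marginal
slopes (Bonferroni-corrected).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf


def fit_allele_level_model(data: pd.DataFrame, min_loci: int = 10):
    """Estimate mean low/high-allele methylation per cell type.

    ``data``: long format with columns ``snp_id``, ``cell_type``
    ("normal"|"cancer"), ``allele_rank`` ("low"|"high"), ``meth``.
    Fixed effects: allele rank, cell type, interaction; random intercept
    and allele-rank slope per locus (REML).  Returns
    ``{(cell_type, allele_rank): estimated mean}`` plus the fit.
    """
    required = {"snp_id", "cell_type", "allele_rank", "meth"}
    if missing := required - set(data.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    n_loci = data["snp_id"].nunique()
    if n_loci < min_loci:
        raise ValueError(
            f"refusing to fit an under-identified model: {n_loci} < {min_loci} loci"
        )
    df = data.copy()
    df["high"] = (df["allele_rank"] == "high").astype(float)
    df["cancer"] = (df["cell_type"] == "cancer").astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "meth ~ high * cancer", df, groups=df["snp_id"], re_formula="~high"
        )
        fit = model.fit(reml=True)
    b = fit.params
    means = {
        ("normal", "low"): float(b["Intercept"]),
        ("normal", "high"): float(b["Intercept"] + b["high"]),
        ("cancer", "low"): float(b["Intercept"] + b["cancer"]),
        ("cancer", "high"): float(
            b["Intercept"] + b["high"] + b["cancer"] + b["high:cancer"]
        ),
    }
    return means, fit


def classify_lom_gom(normal_means, cancer_means, low_thr: float = 0.3,
                     high_thr: float = 0.7) -> str:
    """Classify a per-locus allele configuration change.

    ``LOM``: biallelically high methylation in the normal cell type with
    loss on one allele in cancer; ``GOM``: biallelically low in normal
    with gain on one allele in cancer; anything else ``other``.
    Invariant under allele label swap (means are sorted internally).
    """
    n_low, n_high = sorted(normal_means)
    c_low, c_high = sorted(cancer_means)
    if n_low > high_thr and c_low <= low_thr and c_high > high_thr:
        return "LOM"
    if n_high < low_thr and c_high >= high_thr:
        return "GOM"
    return "other"


def baseline_class_enrichment(target_meth, background_meth,
                              low_thr: float = 0.3, high_thr: float = 0.7):
    """Three-class (low/intermediate/high) baseline-methylation histogram
    of target CpGs vs the all-informative background, with per-class
    Fisher odds ratios.  Empty classes yield ``None`` odds with a warning.
    """
    def classes(v):
        v = np.asarray(v, dtype=float)
        return {
            "low": int((v < low_thr).sum()),
            "intermediate": int(((v >= low_thr) & (v <= high_thr)).sum()),
            "high": int((v > high_thr).sum()),
        }

    t, b = classes(target_meth), classes(background_meth)
    nt, nb = sum(t.values()), sum(b.values())
    rows = []
    for cls in ("low", "intermediate", "high"):
        a, c = t[cls], b[cls]
        if nt == 0 or nb == 0 or (a == 0 and c == 0):
            warnings.warn(f"empty methylation class {cls!r}: OR undefined")
            rows.append(dict(meth_class=cls, n_target=a, n_background=c,
                             odds_ratio=None, p=None))
            continue
        table = [[a, nt - a], [c, nb - c]]
        odds, p = stats.fisher_exact(table)
        rows.append(dict(meth_class=cls, n_target=a, n_background=c,
                         odds_ratio=float(odds), p=float(p)))
    return pd.DataFrame(rows)


def fit_class_interaction_model(data: pd.DataFrame, n_classes: int | None = None,
                                min_total: int = 10, min_per_class: int = 3):
    """Mixed model of allelic methylation difference on affinity
    difference with ASM-class interaction.

    ``data``: columns ``motif_id``, ``score_diff``, ``delta_meth``,
    ``asm_class``.  Motifs with fewer than ``min_total`` occurrences, or
    fewer than ``min_per_class`` in any class, are excluded.  Random
    intercept + slope per motif (REML); per-class marginal slopes with
    Bonferroni-corrected Wald p-values.  On non-convergence the model
    falls back to a random-intercept-only fit (``fallback=True``).
    """
    required = {"motif_id", "score_diff", "delta_meth", "asm_class"}
    if missing := required - set(data.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    classes = sorted(data["asm_class"].unique())
    if n_classes is not None and len(classes) != n_classes:
        raise ValueError(f"expected {n_classes} ASM classes, found {len(classes)}")
    keep = []
    for motif_id, grp in data.groupby("motif_id"):
        if len(grp) < min_total:
            continue
        per_class = grp["asm_class"].value_counts()
        if any(per_class.get(c, 0) < min_per_class for c in classes):
            continue
        keep.append(motif_id)
    df = data[data["motif_id"].isin(keep)].copy()
    if df.empty:
        raise ValueError("no motifs survive the occurrence filters")

    def _fit(re_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "delta_meth ~ score_diff * C(asm_class)", df,
                groups=df["motif_id"], re_formula=re_formula,
            )
            return model.fit(reml=True)

    fallback = False
    try:
        fit = _fit("~score_diff")
        if not fit.converged:
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, ValueError):
        fit = _fit("1")
        fallback = True

    names = list(fit.model.exog_names)
    rows = []
    for ci, cls in enumerate(classes):
        contrast = np.zeros(fit.k_fe)
        contrast[names.index("score_diff")] = 1.0
        inter = f"score_diff:C(asm_class)[T.{cls}]"
        if inter in names:
            contrast[names.index(inter)] = 1.0
        tt = fit.t_test(contrast.reshape(1, -1))
        p = float(np.squeeze(tt.pvalue))
        rows.append(
            dict(
                asm_class=cls,
                slope=float(np.squeeze(tt.effect)),
                se=float(np.squeeze(tt.sd)),
                p_bonferroni=float(min(p * len(classes), 1.0)),
            )
        )
    slopes = pd.DataFrame(rows)
    return slopes, fit, fallback
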