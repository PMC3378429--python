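"""Imputation-quality metrics: true-vs-imputed dosage correlations,
ambiguity profiles, and per-category summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import CATEGORIES, Pedigree, classify_ancestry


def accuracy_correlation(
    true_geno: np.ndarray,
    imputed_dosage: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson correlation between true genotype and imputed dosage for
    one animal, over the masked SNP (or all SNP when ``mask`` is None).

    Returns NaN when either vector has zero variance (e.g. an imputation
    that is constant at twice the allele frequency carries no signal).
    """
    t = np.asarray(true_geno, dtype=float)
    d = np.asarray(imputed_dosage, dtype=float)
    if mask is not None:
        t, d = t[mask], d[mask]
    if t.size < 2 or t.std() == 0 or d.std() == 0:
        return float("nan")
    return float(np.corrcoef(t, d)[0, 1])


def per_animal_accuracy(
    true_geno: np.ndarray,
    dosage: np.ndarray,
    animals: np.ndarray,
    masked_snp: np.ndarray | None = None,
) -> np.ndarray:
    """Correlation per animal over the masked SNP."""
    return np.array(
        [
            accuracy_correlation(true_geno[i], dosage[i], masked_snp)
            for i in animals
        ]
    )


def ambiguity_profile(
    hard_called: np.ndarray, warn_threshold: float = 90.0
) -> pd.DataFrame:
    """Percentage of paternal/maternal alleles called without ambiguity
    (hard 0/1 calls rather than probabilities) per animal.

    Animals whose minimum percentage falls below ``warn_threshold``
    (default 90%, below which imputation accuracy tends to drop) are
    flagged.
    """
    pct = 100.0 * hard_called.mean(axis=1)  # (n, 2)
    out = pd.DataFrame(
        {
            "pct_paternal": pct[:, 0],
            "pct_maternal": pct[:, 1],
        }
    )
    out["pct_min"] = out[["pct_paternal", "pct_maternal"]].min(axis=1)
    out["warn"] = out["pct_min"] < warn_threshold
    return out


def category_summary(
    ped: Pedigree,
    hd_set: set[str],
    animals: np.ndarray,
    correlations: np.ndarray,
    scenario: str = "",
) -> pd.DataFrame:
    """Mean correlation by ancestor category (the Table-1/2 layout):
    per-category count, mean and the N actually entering the mean (NaN
    correlations are excluded but counted)."""
    cats = [classify_ancestry(ped, hd_set, ped.ids[i]) for i in animals]
    df = pd.DataFrame({"category": cats, "correlation": correlations})
    rows = []
    for cat in CATEGORIES:
        sub = df[df.category == cat]
        if len(sub) == 0:
            continue
        valid = sub.correlation.dropna()
        rows.append(
            {
                "scenario": scenario,
                "category": cat,
                "count": len(sub),
                "n_valid": len(valid),
                "mean_correlation": valid.mean() if len(valid) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def plot_report(report: "AccuracyReport", out_dir) -> list:
    """Diagnostic plots: histogram of per-animal correlations, scatter of
    correlation against the minimum percent of unambiguously called
    alleles, and per-category mean bars.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    pa = report.per_animal

    fig, ax = plt.subplots()
    ax.hist(pa.correlation.dropna(), bins=40)
    ax.set_xlabel("true vs imputed correlation")
    ax.set_ylabel("animals")
    paths.append(out_dir / "correlation_hist.png")
    fig.savefig(paths[-1], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.scatter(pa.pct_min, pa.correlation, s=8, alpha=0.5)
    ax.axvline(90, ls="--", color="grey")
    ax.set_xlabel("min % alleles called without ambiguity")
    ax.set_ylabel("correlation")
    paths.append(out_dir / "correlation_vs_ambiguity.png")
    fig.savefig(paths[-1], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    bc = report.by_category
    ax.bar(bc.category, bc.mean_correlation)
    ax.set_ylabel("mean correlation")
    paths.append(out_dir / "category_means.png")
    fig.savefig(paths[-1], dpi=120)
    plt.close(fig)
    return paths


@dataclass
class AccuracyReport:
    """Bundled per-animal metrics and the per-category summary."""

    per_animal: pd.DataFrame
    by_category: pd.DataFrame

    def to_tsv(self, per_animal_path, by_category_path) -> None:
        self.per_animal.to_csv(per_animal_path, sep="\t", index=False)
        self.by_category.to_csv(by_category_path, sep="\t", index=False)


def build_report(
    ped: Pedigree,
    hd_set: set[str],
    animals: np.ndarray,
    true_geno: np.ndarray,
    dosage: np.ndarray,
    hard_called: np.ndarray,
    masked_snp: np.ndarray | None = None,
    scenario: str = "",
) -> AccuracyReport:
    corr = per_animal_accuracy(true_geno, dosage, animals, masked_snp)
    amb = ambiguity_profile(hard_called).iloc[animals].reset_index(drop=True)
    per_animal = pd.DataFrame(
        {
            "id": [ped.ids[i] for i in animals],
            "category": [
                classify_ancestry(ped, hd_set, ped.ids[i]) for i in animals
            ],
            "correlation": corr,
        }
    ).join(amb)
    by_cat = category_summary(ped, hd_set, animals, corr, scenario)
    return AccuracyReport(per_animal=per_animal, by_category=by_cat)
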