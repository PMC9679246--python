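"""Dataset assembly, the PGLS model battery, and species ranking.

This is the orchestration layer: align the species tree, normalized copy
counts and trait table on a common species set (logging every exclusion with
a reason), fit the battery of phylogenetic regressions that make up the
analysis — lifespan ~ body size, TSG ~ OG (all/gatekeeper/caretaker), and
lifespan ~ body size + TSG/OG ratio, each with fixed and ML-optimized
branch-length transforms — and rank species by their TSG/OG ratio.

The central scientific point the battery is built to expose is the *masked
relationship*: because TSG and OG copy numbers are strongly correlated
across species, neither count alone predicts lifespan, but their ratio (or
both together) does.  Marginal lifespan ~ TSG-only / OG-only fits are
included as diagnostics; they are excluded from the Bonferroni family by
default because they are not hypothesis tests, only the exhibit of masking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import pgls
from .phylo_io import PhyloTree, canonical_name
from .traits import log10_transform

logger = logging.getLogger(__name__)

__all__ = [
    "SubsetRules",
    "AnalysisDataset",
    "build_dataset",
    "ModelResult",
    "BatteryReport",
    "run_model_battery",
    "rank_species_by_ratio",
    "load_run_config",
]


@dataclass(frozen=True)
class SubsetRules:
    """Sensitivity-analysis filters applied while building the dataset."""

    drop_families: tuple = ()  # e.g. ("salmonidae", "cyprinidae")
    reliable_only: bool = False
    require_lifespan: bool = True


@dataclass
class AnalysisDataset:
    """Tree, normalized counts and traits aligned on one species list."""

    tree: PhyloTree
    normalized: pd.DataFrame
    traits: pd.DataFrame
    exclusions: pd.DataFrame  # columns: species, reason

    @property
    def species(self) -> list[str]:
        return list(self.normalized.index)

    def n(self) -> int:
        return len(self.normalized)


def build_dataset(
    tree: PhyloTree,
    normalized: pd.DataFrame,
    traits: pd.DataFrame,
    rules: SubsetRules = SubsetRules(),
) -> AnalysisDataset:
    """Intersection join of the three sources with a reasoned exclusion log.

    Exclusion reason codes: ``absent_from_tree``, ``absent_from_counts``,
    ``absent_from_traits``, ``no_lifespan``, ``low_quality``,
    ``family_filter``.  Every species seen in any source lands either in the
    dataset or in the log.
    """
    tree_sp = set(tree.leaf_labels)
    count_sp = set(map(canonical_name, normalized.index))
    trait_sp = set(map(canonical_name, traits.index))
    normalized = normalized.set_axis([canonical_name(s) for s in normalized.index])
    traits = traits.set_axis([canonical_name(s) for s in traits.index])

    excl: list[tuple[str, str]] = []
    all_sp = tree_sp | count_sp | trait_sp
    keep = []
    for sp in sorted(all_sp):
        if sp not in tree_sp:
            excl.append((sp, "absent_from_tree"))
        elif sp not in count_sp:
            excl.append((sp, "absent_from_counts"))
        elif sp not in trait_sp:
            excl.append((sp, "absent_from_traits"))
        elif rules.require_lifespan and pd.isna(traits.loc[sp, "max_lifespan_y"]):
            excl.append((sp, "no_lifespan"))
        elif rules.reliable_only and traits.loc[sp, "source_quality"] != "reliable":
            excl.append((sp, "low_quality"))
        elif str(traits.loc[sp, "family"]).lower() in {f.lower() for f in rules.drop_families}:
            excl.append((sp, "family_filter"))
        else:
            keep.append(sp)
    for sp, reason in excl:
        logger.info("excluded %s: %s", sp, reason)
    if len(keep) < 3:
        raise ValueError(f"species intersection too small after filters: {len(keep)} < 3")
    pruned = tree.prune_to_taxa(keep)
    # order everything by the pruned tree's leaf order
    order = pruned.leaf_labels
    return AnalysisDataset(
        tree=pruned,
        normalized=normalized.loc[order],
        traits=traits.loc[order],
        exclusions=pd.DataFrame(excl, columns=["species", "reason"]),
    )


# ---------------------------------------------------------------------------
# Model battery
# ---------------------------------------------------------------------------

MAIN_MODELS = (
    ("lifespan_vs_bodysize", "log_lifespan", ("log_length",)),
    ("tsg_vs_og", "z_tsg", ("z_og",)),
    ("gatekeeper_vs_og", "z_gatekeeper", ("z_og",)),
    ("caretaker_vs_og", "z_caretaker", ("z_og",)),
    ("lifespan_vs_bodysize_ratio", "log_lifespan", ("log_length", "ratio_tsg_og")),
)

DIAGNOSTIC_MODELS = (
    ("lifespan_vs_tsg_only", "log_lifespan", ("z_tsg",)),
    ("lifespan_vs_og_only", "log_lifespan", ("z_og",)),
)


@dataclass
class ModelResult:
    name: str
    variant: str  # fixed | optimized
    diagnostic: bool
    fit: pgls.PGLSFit | None
    error: str | None = None
    n: int = 0


@dataclass
class BatteryReport:
    """All model fits from one run plus the multiplicity correction."""

    results: list
    alpha: float
    m_tests: int
    bonferroni: float

    def get(self, name: str, variant: str = "fixed") -> ModelResult:
        for r in self.results:
            if r.name == name and r.variant == variant:
                return r
        raise KeyError(f"no model {name}/{variant}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            if r.fit is None:
                rows.append(
                    {"model": r.name, "variant": r.variant, "diagnostic": r.diagnostic, "n": r.n, "error": r.error}
                )
                continue
            t = r.fit.transforms
            for i, term in enumerate(r.fit.terms):
                rows.append(
                    {
                        "model": r.name,
                        "variant": r.variant,
                        "diagnostic": r.diagnostic,
                        "term": term,
                        "Estimate": r.fit.coefficients[i],
                        "SE": r.fit.standard_errors[i],
                        "t": r.fit.t_values[i],
                        "p": r.fit.p_values[i],
                        "r_squared": r.fit.r_squared,
                        "kappa": t.kappa,
                        "lambda": t.lam,
                        "delta": t.delta,
                        "n": r.n,
                        "significant_bonferroni": bool(
                            (not r.diagnostic) and term != "intercept" and r.fit.p_values[i] <= self.bonferroni
                        ),
                        "error": None,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"model battery: {self.m_tests} tests, alpha={self.alpha}, Bonferroni threshold={self.bonferroni:.5g}"]
        for r in self.results:
            head = f"--- {r.name} [{r.variant}]" + (" (diagnostic)" if r.diagnostic else "")
            if r.fit is None:
                lines.append(f"{head}: FAILED ({r.error})")
            else:
                lines.append(head)
                lines.append(r.fit.summary())
        return "\n".join(lines)


def _model_frame(dataset: AnalysisDataset) -> pd.DataFrame:
    df = dataset.normalized.copy()
    df["log_length"] = log10_transform(dataset.traits["max_length_cm"]).reindex(df.index)
    life = dataset.traits["max_lifespan_y"]
    df["log_lifespan"] = np.log10(life.where(life > 0)).reindex(df.index)
    return df


def run_model_battery(
    dataset: AnalysisDataset,
    transform_mode: str = "both",  # fixed | ml | both
    include_diagnostics: bool = True,
    alpha: float = 0.05,
    m_tests: int | None = None,
) -> BatteryReport:
    """Fit the full model battery on one dataset.

    Each model drops species with missing variables and records its own n.
    ``m_tests`` defaults to the number of non-diagnostic model fits in this
    run (the Bonferroni family is what the run actually tested); pass 39 to
    reproduce the main-plus-supplementary family size of the original fish
    analysis.  Individual model failures are recorded per model, never
    propagated.
    """
    if transform_mode not in ("fixed", "ml", "both"):
        raise ValueError(f"transform_mode must be fixed/ml/both, got {transform_mode}")
    frame = _model_frame(dataset)
    variants = {"fixed": ("fixed",), "ml": ("optimized",), "both": ("fixed", "optimized")}[transform_mode]
    jobs = list(MAIN_MODELS) + (list(DIAGNOSTIC_MODELS) if include_diagnostics else [])
    diag_names = {name for name, *_ in DIAGNOSTIC_MODELS}

    results: list[ModelResult] = []
    for name, response, predictors in jobs:
        cols = [response, *predictors]
        sub = frame[cols].dropna()
        for variant in variants:
            res = ModelResult(name=name, variant=variant, diagnostic=name in diag_names, fit=None, n=len(sub))
            try:
                if len(sub) < len(predictors) + 2:
                    raise ValueError(f"too few complete cases (n={len(sub)}, k={len(predictors) + 1})")
                subtree = dataset.tree.prune_to_taxa(list(sub.index))
                order = subtree.leaf_labels
                sub_o = sub.loc[order]
                X = np.column_stack([np.ones(len(sub_o))] + [sub_o[p].to_numpy() for p in predictors])
                y = sub_o[response].to_numpy()
                terms = ["intercept", *predictors]
                if variant == "fixed":
                    V = pgls.vcv_from_tree(subtree)
                    res.fit = pgls.gls_fit(X, y, V, terms=terms)
                else:
                    _, res.fit = pgls.optimize_transforms(subtree, X, y, terms=terms)
            except Exception as exc:  # report per-model, keep the battery running
                res.error = str(exc)
                logger.warning("model %s [%s] failed: %s", name, variant, exc)
            results.append(res)

    if m_tests is None:
        m_tests = sum(1 for r in results if not r.diagnostic)
    bonf = pgls.bonferroni_threshold(alpha, m_tests)
    return BatteryReport(results=results, alpha=alpha, m_tests=m_tests, bonferroni=bonf)


def rank_species_by_ratio(normalized: pd.DataFrame, top_k: int = 5) -> pd.DataFrame:
    """Species ordered by descending TSG/OG ratio.

    Returns the full ordered table with the ratio rounded to 3 decimals for
    reporting, a ``rank`` column, a ``tie`` flag (set where the rounded ratio
    is shared), and ``group`` marking the top-k / bottom-k species.  Ties
    break lexicographically on the species name.
    """
    df = normalized[["ratio_tsg_og"]].copy()
    df.index.name = "species"
    df["ratio_3dp"] = df["ratio_tsg_og"].round(3)
    df = (
        df.reset_index()
        .sort_values(["ratio_tsg_og", "species"], ascending=[False, True], kind="mergesort")
        .set_index("species")
    )
    df["rank"] = range(1, len(df) + 1)
    df["tie"] = df["ratio_tsg_og"].duplicated(keep=False)
    n = len(df)
    group = pd.Series("", index=df.index)
    group.iloc[: min(top_k, n)] = "top"
    group.iloc[max(n - top_k, 0) :] = "bottom"
    df["group"] = group
    return df


def load_run_config(path) -> dict:
    """Read a YAML or JSON run configuration (paths, subset rules, mode, seed)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
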