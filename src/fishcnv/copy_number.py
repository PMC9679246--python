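"""Cancer-gene classification, per-species copy counting, and normalization.

The analysis rests on counting copies of human cancer-gene orthologs in each
species' genome.  Genes come from a COSMIC-census-style table and are
partitioned by role (tumour suppressor, oncogene, fusion); copies are counted
either from CAFE-style gene trees or from ortholog record tables; raw sums
are normalized to copies-per-found-gene so incomplete assemblies do not drag
species down; and the normalized tumour-suppressor and oncogene values are
combined into the TSG/OG ratio and z-scores used in the regressions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo_io import canonical_name, extract_cafe_counts

logger = logging.getLogger(__name__)

__all__ = [
    "GeneClassification",
    "GeneCountTable",
    "classify_cosmic",
    "read_cosmic_csv",
    "read_gatekeeper_caretaker",
    "gene_subset",
    "counts_from_gene_trees",
    "counts_from_ortholog_records",
    "normalize_counts",
    "tsg_og_ratio",
    "zscore",
    "build_normalized_counts",
]

ROLE_TSG = "TSG"
ROLE_OG = "OG"
ROLE_FUSION = "FUSION"

_ROLE_TOKENS = {
    "tsg": ROLE_TSG,
    "tumour suppressor": ROLE_TSG,
    "tumor suppressor": ROLE_TSG,
    "oncogene": ROLE_OG,
    "og": ROLE_OG,
    "fusion": ROLE_FUSION,
}


@dataclass(frozen=True)
class GeneClassification:
    """Role assignment for one cancer gene.

    ``tsg_class`` distinguishes gatekeepers (directly restrain tumour growth)
    from caretakers (maintain genome integrity); it is 'unknown' unless the
    gene is a TSG listed in a gatekeeper/caretaker annotation file.
    """

    gene_symbol: str
    roles: frozenset
    tier: int
    tsg_class: str = "unknown"  # gatekeeper | caretaker | unknown
    mutation_origin: frozenset = frozenset()

    def __post_init__(self):
        if not self.roles:
            raise ValueError(f"{self.gene_symbol}: roles must be nonempty")
        if self.tier not in (1, 2):
            raise ValueError(f"{self.gene_symbol}: tier must be 1 or 2, got {self.tier}")
        if self.tsg_class not in ("gatekeeper", "caretaker", "unknown"):
            raise ValueError(f"{self.gene_symbol}: bad tsg_class {self.tsg_class!r}")
        if self.tsg_class != "unknown" and ROLE_TSG not in self.roles:
            raise ValueError(f"{self.gene_symbol}: tsg_class set on a non-TSG gene")

    @property
    def bucket(self) -> str:
        """Exclusive role bucket: pure_tsg | pure_og | both | all | pure_fusion | tsg_fusion | og_fusion."""
        r = self.roles
        if r == {ROLE_TSG}:
            return "pure_tsg"
        if r == {ROLE_OG}:
            return "pure_og"
        if r == {ROLE_FUSION}:
            return "pure_fusion"
        if r == {ROLE_TSG, ROLE_OG}:
            return "both"
        if r == {ROLE_TSG, ROLE_OG, ROLE_FUSION}:
            return "all"
        if r == {ROLE_TSG, ROLE_FUSION}:
            return "tsg_fusion"
        return "og_fusion"


def _parse_roles(role_string: str) -> frozenset:
    tokens = [t.strip().lower() for t in re.split(r"[,;/]", str(role_string)) if t.strip()]
    roles = {_ROLE_TOKENS[t] for t in tokens if t in _ROLE_TOKENS}
    if len(roles) < len(set(tokens)):
        unknown = [t for t in tokens if t not in _ROLE_TOKENS]
        if unknown:
            logger.warning("unrecognized role tokens %s in %r", unknown, role_string)
    return frozenset(roles)


def classify_cosmic(
    records: pd.DataFrame,
    gatekeeper_caretaker: Mapping[str, str] | None = None,
) -> tuple[list[GeneClassification], dict[str, int], list[str]]:
    """Partition a COSMIC-census-like table into exclusive role buckets.

    ``records`` needs columns ``gene``, ``role``, ``tier`` and optionally
    ``somatic``/``germline`` flags.  Returns the classifications, a tally per
    bucket (pure_tsg, pure_og, both, all, pure_fusion, tsg_fusion, og_fusion,
    unclassified), and the list of genes whose role string could not be
    interpreted (kept out of every analysis subset but never silently
    dropped).
    """
    classifications: list[GeneClassification] = []
    unclassified: list[str] = []
    gk = {k.upper(): v for k, v in (gatekeeper_caretaker or {}).items()}
    tallies = {
        b: 0
        for b in ("pure_tsg", "pure_og", "both", "all", "pure_fusion", "tsg_fusion", "og_fusion", "unclassified")
    }
    for row in records.itertuples(index=False):
        gene = str(row.gene).strip()
        roles = _parse_roles(row.role)
        if not roles:
            unclassified.append(gene)
            tallies["unclassified"] += 1
            logger.warning("gene %s has empty/unrecognized role %r; routed to 'unclassified'", gene, row.role)
            continue
        origin = set()
        if getattr(row, "somatic", None) in (1, True, "yes", "y"):
            origin.add("somatic")
        if getattr(row, "germline", None) in (1, True, "yes", "y"):
            origin.add("germline")
        tsg_class = "unknown"
        if ROLE_TSG in roles and gene.upper() in gk:
            tsg_class = gk[gene.upper()]
        cls = GeneClassification(
            gene_symbol=gene,
            roles=roles,
            tier=int(row.tier),
            tsg_class=tsg_class,
            mutation_origin=frozenset(origin),
        )
        classifications.append(cls)
        tallies[cls.bucket] += 1
    return classifications, tallies, unclassified


def read_cosmic_csv(path) -> pd.DataFrame:
    """Read a COSMIC-census-like CSV into the canonical column layout.

    Accepts either the census headers (``Gene Symbol``, ``Role in Cancer``,
    ``Tier``, ``Somatic``, ``Germline``) or the already-canonical lowercase
    names.
    """
    df = pd.read_csv(path)
    renames = {
        "Gene Symbol": "gene",
        "Role in Cancer": "role",
        "Tier": "tier",
        "Somatic": "somatic",
        "Germline": "germline",
    }
    df = df.rename(columns=renames)
    missing = {"gene", "role", "tier"} - set(df.columns)
    if missing:
        raise ValueError(f"COSMIC table missing columns: {sorted(missing)}")
    return df


def read_gatekeeper_caretaker(path) -> dict[str, str]:
    """Two-column TSV (gene, class) with class in {gatekeeper, caretaker}."""
    df = pd.read_csv(path, sep="\t", header=0, names=["gene", "tsg_class"])
    out: dict[str, str] = {}
    for row in df.itertuples(index=False):
        cls = str(row.tsg_class).strip().lower()
        if cls not in ("gatekeeper", "caretaker"):
            raise ValueError(f"gene {row.gene}: tsg_class must be gatekeeper/caretaker, got {cls!r}")
        out[str(row.gene).strip().upper()] = cls
    return out


def gene_subset(
    classifications: Sequence[GeneClassification],
    role: str,
    tier_max: int = 2,
    tsg_class: str | None = None,
    include_fusion_mixed: bool = False,
) -> list[str]:
    """Gene symbols counted toward a role tally.

    Genes annotated as both TSG and oncogene are always excluded from both
    tallies.  Mixed role+fusion genes (e.g. ``{TSG, fusion}``) enter only in
    ``include_fusion_mixed`` mode (default off: strict pure-role counting).
    ``tsg_class`` restricts TSGs to gatekeepers or caretakers.
    """
    if role not in (ROLE_TSG, ROLE_OG):
        raise ValueError(f"role must be {ROLE_TSG} or {ROLE_OG}")
    allowed_buckets = {"pure_tsg"} if role == ROLE_TSG else {"pure_og"}
    if include_fusion_mixed:
        allowed_buckets.add("tsg_fusion" if role == ROLE_TSG else "og_fusion")
    out = []
    for cls in classifications:
        if cls.bucket not in allowed_buckets or cls.tier > tier_max:
            continue
        if tsg_class is not None and cls.tsg_class != tsg_class:
            continue
        out.append(cls.gene_symbol)
    return out


# ---------------------------------------------------------------------------
# Copy-count tables
# ---------------------------------------------------------------------------


@dataclass
class GeneCountTable:
    """Integer copy counts (genes x species) plus a found mask.

    ``found[g, s]`` records whether any ortholog evidence existed for the
    pair at all; a gene that was looked for and not found is ``found`` with
    count 0, which is distinct from a gene for which the source carried no
    record (treated as missing, never as zero).
    """

    counts: pd.DataFrame  # int, genes x species
    found: pd.DataFrame  # bool, same shape

    def __post_init__(self):
        if not self.counts.index.equals(self.found.index) or not self.counts.columns.equals(self.found.columns):
            raise ValueError("counts and found must share index (genes) and columns (species)")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("copy counts must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, counts_path, found_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        self.found.astype(int).to_csv(found_path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, counts_path, found_path) -> "GeneCountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
        found = pd.read_csv(found_path, sep="\t", index_col="gene").astype(bool)
        return cls(counts=counts.astype(int), found=found)


def counts_from_gene_trees(
    gene_trees: Mapping[str, str],
    species: Sequence[str],
    count_pattern=None,
) -> GeneCountTable:
    """Assemble a count table from CAFE-style gene trees (one per gene).

    ``found`` is true exactly where the species appears as a leaf of that
    gene's tree.
    """
    if len(species) == 0:
        raise ValueError("species list must be nonempty")
    species = [canonical_name(s) for s in species]
    genes = list(gene_trees)
    counts = pd.DataFrame(0, index=genes, columns=species, dtype=int)
    found = pd.DataFrame(False, index=genes, columns=species, dtype=bool)
    for gene, text in gene_trees.items():
        kwargs = {} if count_pattern is None else {"count_pattern": count_pattern}
        per_species = extract_cafe_counts(text, **kwargs)
        for sp, n in per_species.items():
            if sp in found.columns:
                counts.loc[gene, sp] = n
                found.loc[gene, sp] = True
    return GeneCountTable(counts=counts, found=found)


def counts_from_ortholog_records(
    records: pd.DataFrame,
    species: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> GeneCountTable:
    """Assemble a count table from an ortholog-record table.

    ``records`` has columns ``gene``, ``species``, ``ortholog_id``,
    ``confidence`` (binary).  The count is the number of *distinct* confident
    ortholog ids per (gene, species); duplicated rows count once.  ``found``
    is true wherever any record exists, confident or not.
    """
    required = {"gene", "species", "ortholog_id", "confidence"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"ortholog records missing columns: {sorted(missing)}")
    rec = records.copy()
    rec["species"] = rec["species"].map(canonical_name)
    if genes is None:
        genes = sorted(rec["gene"].unique())
    if species is None:
        species = sorted(rec["species"].unique())
    else:
        species = [canonical_name(s) for s in species]
    counts = pd.DataFrame(0, index=list(genes), columns=list(species), dtype=int)
    found = pd.DataFrame(False, index=list(genes), columns=list(species), dtype=bool)
    confident = rec[rec["confidence"].astype(int) == 1]
    n_conf = (
        confident.drop_duplicates(["gene", "species", "ortholog_id"])
        .groupby(["gene", "species"])
        .size()
    )
    for (g, s), n in n_conf.items():
        if g in counts.index and s in counts.columns:
            counts.loc[g, s] = int(n)
    for g, s in rec[["gene", "species"]].drop_duplicates().itertuples(index=False):
        if g in found.index and s in found.columns:
            found.loc[g, s] = True
    return GeneCountTable(counts=counts, found=found)


def normalize_counts(table: GeneCountTable, genes: Iterable[str]) -> pd.Series:
    """Copies per found gene, per species, over a gene subset.

    For species *s*: sum of counts over genes in the subset that were found
    in *s*, divided by the number of such found genes.  This compensates for
    incomplete assemblies: a species missing half its orthologs from poor
    sequencing is not scored as having half the copies.  Species where no
    subset gene was found are omitted (with a warning), not scored 0.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene subset must be nonempty")
    present = [g for g in genes if g in table.counts.index]
    if not present:
        raise ValueError("gene subset is disjoint from the count table")
    counts = table.counts.loc[present]
    found = table.found.loc[present]
    num = counts.where(found, 0).sum(axis=0)
    den = found.sum(axis=0)
    empty = den[den == 0].index.tolist()
    if empty:
        logger.warning("species with zero found genes omitted from normalization: %s", empty)
    keep = den > 0
    return (num[keep] / den[keep]).astype(float)


def tsg_og_ratio(norm_tsg: float | pd.Series, norm_og: float | pd.Series):
    """Normalized TSG count divided by normalized OG count.

    The ratio is scale-free: a whole-genome duplication doubles both
    normalized counts and leaves it unchanged, which is what lets
    salmonids/cyprinids be compared with unduplicated lineages.  Undefined
    (error) when the OG normalization is not positive.
    """
    og = np.asarray(norm_og, dtype=float)
    if np.any(og <= 0):
        raise ValueError("TSG/OG ratio undefined where normalized OG count <= 0")
    return norm_tsg / norm_og


def zscore(values: pd.Series) -> pd.Series:
    """Standardize to mean 0, sample SD 1 (n-1 denominator)."""
    values = values.astype(float)
    if values.nunique() < 2:
        raise ValueError("zscore undefined for constant input (SD = 0)")
    sd = values.std(ddof=1)
    return (values - values.mean()) / sd


def build_normalized_counts(
    table: GeneCountTable,
    classifications: Sequence[GeneClassification],
    tier_max: int = 2,
    include_fusion_mixed: bool = False,
) -> pd.DataFrame:
    """Per-species normalized counts, ratio, and z-scores for the model battery.

    Columns: norm_tsg, norm_og, norm_gatekeeper, norm_caretaker,
    ratio_tsg_og, z_tsg, z_og, z_gatekeeper, z_caretaker.  Standardization is
    over all species present in the table (the full ingested set), so later
    per-model subsets reuse a single common scale.  The ratio itself is not
    standardized.
    """
    subsets = {
        "tsg": gene_subset(classifications, ROLE_TSG, tier_max, None, include_fusion_mixed),
        "og": gene_subset(classifications, ROLE_OG, tier_max, None, include_fusion_mixed),
        "gatekeeper": gene_subset(classifications, ROLE_TSG, tier_max, "gatekeeper", include_fusion_mixed),
        "caretaker": gene_subset(classifications, ROLE_TSG, tier_max, "caretaker", include_fusion_mixed),
    }
    cols = {}
    for name, genes in subsets.items():
        cols[f"norm_{name}"] = normalize_counts(table, genes)
    out = pd.DataFrame(cols)
    out["ratio_tsg_og"] = tsg_og_ratio(out["norm_tsg"], out["norm_og"])
    for name in subsets:
        out[f"z_{name}"] = zscore(out[f"norm_{name}"].dropna()).reindex(out.index)
    out.index.name = "species"
    return out
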