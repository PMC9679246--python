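"""Life-history trait ingestion, log transforms, and the longevity quotient.

Maximum body length (cm) and maximum lifespan (years) are the life-history
axes of the analysis; body mass (g) enters only through the longevity
quotient.  Both length and lifespan are log10-transformed before regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_traits",
    "validate_traits",
    "log10_transform",
    "longevity_quotient",
]

from .phylo_io import canonical_name

TRAIT_COLUMNS = ["max_length_cm", "max_lifespan_y", "body_mass_g", "source_quality", "family"]


def read_traits(path) -> pd.DataFrame:
    """Read a traits CSV (species, max_length_cm, max_lifespan_y, body_mass_g,
    source_quality, family) into a species-indexed frame.

    Missing values are empty fields; species names are canonicalized.
    """
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("traits CSV must have a 'species' column")
    df["species"] = df["species"].map(canonical_name)
    df = df.set_index("species")
    for col in TRAIT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col not in ("source_quality", "family") else ""
    return validate_traits(df[TRAIT_COLUMNS])


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate species in trait table: {dups}")
    for col in ("max_length_cm", "max_lifespan_y", "body_mass_g"):
        vals = df[col]
        bad = vals[(vals.notna()) & (vals <= 0)]
        if len(bad):
            raise ValueError(f"nonpositive {col} for species: {sorted(bad.index)}")
    quality = df["source_quality"].fillna("")
    unknown = set(quality.unique()) - {"reliable", "low", ""}
    if unknown:
        raise ValueError(f"source_quality must be 'reliable' or 'low', got {sorted(unknown)}")
    return df


def log10_transform(values: pd.Series) -> pd.Series:
    """Elementwise log10; errors name the offending species."""
    vals = values.dropna().astype(float)
    bad = vals[vals <= 0]
    if len(bad):
        raise ValueError(f"log10 undefined for nonpositive values of: {sorted(bad.index)}")
    return np.log10(vals)


def longevity_quotient(traits: pd.DataFrame) -> pd.Series:
    """Observed / allometrically expected maximum lifespan per species.

    Expected lifespan comes from an ordinary least-squares fit of
    log10(max lifespan) on log10(body mass) over the species with both
    values; LQ_i = lifespan_i / 10^(a + b log10(mass_i)).  LQ > 1 marks
    species living longer than their mass predicts.  The fit is in-sample
    (each species contributes to its own expectation), matching the usual
    comparative-longevity convention; mean log10(LQ) over fitted species is
    therefore exactly 0.  Species lacking mass or lifespan get no LQ.
    """
    have = traits[["max_lifespan_y", "body_mass_g"]].dropna()
    if len(have) < 3:
        raise ValueError(f"longevity quotient needs >= 3 species with lifespan and mass, got {len(have)}")
    log_mass = np.log10(have["body_mass_g"].astype(float))
    if log_mass.nunique() < 2:
        raise ValueError("longevity quotient needs body-mass variation")
    log_life = np.log10(have["max_lifespan_y"].astype(float))
    slope, intercept = np.polyfit(log_mass, log_life, 1)
    expected = 10 ** (intercept + slope * log_mass)
    lq = have["max_lifespan_y"] / expected
    lq.name = "longevity_quotient"
    return lq
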