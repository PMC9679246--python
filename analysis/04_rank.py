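"""Rank species by TSG/OG ratio: which genomes invest most in tumour suppression.

Because the ratio is invariant to whole-genome duplication, salmonid-like
WGD species are directly comparable with unduplicated lineages.  Writes
results/ranking.csv and prints the top and bottom five.
"""

import argparse
from pathlib import Path

import pandas as pd

from fishcnv import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--top-k", type=int, default=5)
    args = ap.parse_args()

    normalized = pd.read_csv(args.outdir / "normalized.csv", index_col="species")
    ranked = pipeline.rank_species_by_ratio(normalized, top_k=args.top_k)
    ranked.to_csv(args.outdir / "ranking.csv")

    show = ranked[ranked["group"] != ""][["ratio_3dp", "rank", "group", "tie"]]
    print(f"TSG/OG ratio ranking ({len(ranked)} species):")
    print(show.to_string())
    if ranked["tie"].any():
        print("note: ties broken lexicographically (flagged in the 'tie' column)")
    print(f"wrote {args.outdir / 'ranking.csv'}")


if __name__ == "__main__":
    main()
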