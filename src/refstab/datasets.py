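"""Packaged published data from the oat reference-gene study.

Two small tables travel with the package:

* the per-algorithm stability rank orders of ten candidate reference genes
  across four experimental sample sets of hexaploid oat (all samples,
  seedlings, developing seeds, developing endosperms), used to exercise the
  geometric-mean consensus ranking offline;
* the qPCR primer pairs for the eleven oat candidates with their reported
  amplicon lengths, amplification efficiencies and transcript copy numbers
  (four of the candidates are duplicated genes).

The raw Ct measurements behind the rank orders were never deposited, so
score-level reproduction is out of reach; the rank orders themselves are
the published inputs the consensus step consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .dupregion import PrimerPair

__all__ = ["PublishedPrimer", "published_rank_orders", "published_primers"]

SAMPLE_SETS = ("all_samples", "seedlings", "seeds", "endosperms")
METHODS = ("deltact", "genorm", "normfinder", "bestkeeper")


@dataclass(frozen=True)
class PublishedPrimer:
    pair: PrimerPair
    amplicon_length: int
    efficiency_percent: float | None
    n_copies: int


def _data(name: str) -> pd.DataFrame:
    with resources.files("refstab.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def published_rank_orders() -> dict[str, dict[str, dict[str, float]]]:
    """Published per-algorithm rank maps: sample_set -> method -> gene -> rank."""
    df = _data("oat_published_ranks.tsv")
    out: dict[str, dict[str, dict[str, float]]] = {}
    for (sset, method), grp in df.groupby(["sample_set", "method"], sort=False):
        out.setdefault(sset, {})[method] = {
            g: float(r) for g, r in zip(grp["gene"], grp["rank"])
        }
    return out


def published_scores() -> pd.DataFrame:
    """Published per-gene stability scores (long frame) alongside the ranks."""
    return _data("oat_published_ranks.tsv")


def published_primers() -> dict[str, PublishedPrimer]:
    """Published primer pairs keyed by gene, with amplicon lengths."""
    df = _data("oat_published_primers.tsv")
    out = {}
    for _, row in df.iterrows():
        eff = row["efficiency_percent"]
        out[row["name"]] = PublishedPrimer(
            pair=PrimerPair(
                name=row["name"], forward=row["forward"], reverse=row["reverse"]
            ),
            amplicon_length=int(row["amplicon_length"]),
            efficiency_percent=None if pd.isna(eff) else float(eff),
            n_copies=int(row["n_copies"]),
        )
    return out
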