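"""Published summary tables for bacterial GC-content jump analysis.

These are the headline per-clade numbers from the published survey of
GC-content evolution across ten order-level clades of Bacteroidetes and
Proteobacteria (GTDB release 80): maximum log-likelihoods of the three
trait models, clade sizes, ancestral GC estimates, and called-jump tallies
with their (downward, upward) splits, plus the host-association-switch
contingency counts.  They serve as worked-example inputs — the underlying
genome-scale phylogenies are not shipped — for the direction-tally and
exact-test machinery in :mod:`gcjump.ecology`.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "clade_summary",
    "host_switch_table",
    "direction_totals",
]

_CLADE_ROWS = [
    # clade, phylum, ml_bm, ml_ou, ml_levy, n_taxa, ancestral_gc, n_jumps, n_down, n_up
    ("Cytophagales", "Bacteroidetes", -445.252, -445.252, -426.24, 167, 40.07, 2, 1, 1),
    ("Bacteroidales", "Bacteroidetes", -1886.49, -1886.49, -1831.52, 713, 40.10, 3, 0, 3),
    ("Flavobacteriales", "Bacteroidetes", -1364.19, -1364.19, -1204.14, 609, 39.89, 73, 19, 54),
    ("Acetobacterales", "Proteobacteria (alpha)", -572.371, -572.371, -537.383, 198, 62.84, 7, 6, 1),
    ("Sphingomonadales", "Proteobacteria (alpha)", -540.688, -540.688, -471.786, 260, 55.84, 11, 9, 2),
    ("Rhizobiales", "Proteobacteria (alpha)", -1040.84, -1040.84, -863.626, 538, 63.80, 23, 17, 6),
    ("Rhodobacterales", "Proteobacteria (alpha)", -1141.83, -1141.83, -1033.02, 469, 63.38, 27, 20, 7),
    ("Betaproteobacteriales", "Proteobacteria (gamma)", -1859.95, -1859.949, -1690.86, 770, 58.12, 24, 20, 4),
    ("Enterobacterales", "Proteobacteria (gamma)", -1441.81, -1440.58, -1314.91, 602, 45.99, 18, 7, 11),
    ("Pseudomonadales", "Proteobacteria (gamma)", -1485.58, -1485.572, -1406.66, 632, 52.02, 13, 11, 2),
]


def clade_summary() -> pd.DataFrame:
    """Per-clade model log-likelihoods and called-jump tallies."""
    return pd.DataFrame(
        _CLADE_ROWS,
        columns=[
            "clade",
            "phylum",
            "ml_bm",
            "ml_ou",
            "ml_levy",
            "n_taxa",
            "ancestral_gc",
            "n_jumps",
            "n_down",
            "n_up",
        ],
    )


def host_switch_table():
    """Direction x host-association-switch counts among the jumps with
    curated lifestyle data: rows (free-living -> host-associated,
    host-associated -> free-living), columns (down, up)."""
    from .ecology import ContingencyTable2x2

    return ContingencyTable2x2(a=15, b=4, c=4, d=8)


def direction_totals() -> dict:
    """Direction tallies among the 91 jumps with curated habitat data."""
    return {"n_down": 48, "n_up": 43, "n_total": 91}
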