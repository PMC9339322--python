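"""Ecological context of jumps: lifestyle-switch classification, direction
tallies, and an exact 2x2 test of direction x lifestyle association.

Annotations use closed vocabularies; missing information is an explicit
``unknown`` — records with unknown values propagate to the ``unknown``
category and are excluded from tallies rather than guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GCJumpError

__all__ = [
    "HOST_STATUSES",
    "OXYGEN_CLASSES",
    "EcologyAnnotation",
    "ContingencyTable2x2",
    "FisherResult",
    "classify_switch",
    "tally_directions",
    "fisher_exact_2x2",
    "read_annotation_table",
    "write_annotation_table",
]

HOST_STATUSES = ("host_dependent", "host_associated", "not_host_dependent", "unknown")
#: Ordered oxygen-dependence scale; "aerobic" and "obligately_aerobic" share
#: a rank, so a move between them is not an oxygen change.
OXYGEN_CLASSES = ("anaerobic", "facultative", "aerobic", "obligately_aerobic", "unknown")
_OXYGEN_RANK = {"anaerobic": 0, "facultative": 1, "aerobic": 2, "obligately_aerobic": 2}

_HOSTY = {"host_dependent", "host_associated"}


@dataclass
class EcologyAnnotation:
    """Per-jump ecological context of the affected clade and its sister.

    Host status and oxygen class are majority-rule assignments per clade
    (ties -> ``unknown``); ``marine`` marks affected taxa isolated from
    marine habitats.
    """

    host_status_affected: str = "unknown"
    host_status_sister: str = "unknown"
    marine: bool = False
    oxygen_affected: str = "unknown"
    oxygen_sister: str = "unknown"

    def __post_init__(self):
        for v in (self.host_status_affected, self.host_status_sister):
            if v not in HOST_STATUSES:
                raise GCJumpError(f"invalid host status '{v}' (use one of {HOST_STATUSES})")
        for v in (self.oxygen_affected, self.oxygen_sister):
            if v not in OXYGEN_CLASSES:
                raise GCJumpError(f"invalid oxygen class '{v}' (use one of {OXYGEN_CLASSES})")


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = lifestyle-switch direction, columns =
    jump direction (down, up)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise GCJumpError("contingency counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise GCJumpError("contingency table is all zero")


@dataclass
class FisherResult:
    p_two_sided: float
    odds_ratio: float


def classify_switch(annotation: EcologyAnnotation) -> set[str]:
    """Deterministic multi-label lifestyle classification of one jump.

    Labels: ``obligate_host`` (affected clade obligately host-dependent),
    ``host_gain`` (affected host-associated or -dependent, sister free
    living), ``host_loss`` (the reverse), ``no_switch`` (both host statuses
    known, neither pattern), ``marine``, ``oxygen_up`` / ``oxygen_down``
    (movement on the ordered oxygen scale), and ``unknown`` whenever a
    needed status is unknown.
    """
    a = annotation
    labels: set[str] = set()
    if a.host_status_affected == "unknown" or a.host_status_sister == "unknown":
        labels.add("unknown")
    else:
        if a.host_status_affected == "host_dependent":
            labels.add("obligate_host")
        if a.host_status_affected in _HOSTY and a.host_status_sister == "not_host_dependent":
            labels.add("host_gain")
        elif a.host_status_affected == "not_host_dependent" and a.host_status_sister in _HOSTY:
            labels.add("host_loss")
        elif not labels:
            labels.add("no_switch")
    if a.marine:
        labels.add("marine")
    if a.oxygen_affected == "unknown" or a.oxygen_sister == "unknown":
        labels.add("unknown")
    else:
        ra = _OXYGEN_RANK[a.oxygen_affected]
        rs = _OXYGEN_RANK[a.oxygen_sister]
        if ra > rs:
            labels.add("oxygen_up")
        elif ra < rs:
            labels.add("oxygen_down")
    return labels


def tally_directions(records: list[tuple[str, set[str]]]) -> pd.DataFrame:
    """Per-category counts of downward/upward jumps.

    ``records`` pairs a jump direction ("down"/"up"; "zero" tallied under
    its own column) with the category labels from :func:`classify_switch`.
    Display percentages are rounded half-up to integers; the unrounded
    values are retained alongside.
    """
    cats: dict[str, dict[str, int]] = {}
    for direction, labels in records:
        for lab in labels:
            c = cats.setdefault(lab, {"down": 0, "up": 0, "zero": 0})
            if direction not in c:
                raise GCJumpError(f"invalid jump direction '{direction}'")
            c[direction] += 1
    rows = []
    for lab in sorted(cats):
        c = cats[lab]
        total = c["down"] + c["up"]
        pct_down = 100.0 * c["down"] / total if total else float("nan")
        pct_up = 100.0 * c["up"] / total if total else float("nan")
        rows.append(
            {
                "category": lab,
                "n_down": c["down"],
                "n_up": c["up"],
                "n_zero": c["zero"],
                "pct_down": pct_down,
                "pct_up": pct_up,
                "pct_down_display": int(math.floor(pct_down + 0.5)) if total else 0,
                "pct_up_display": int(math.floor(pct_up + 0.5)) if total else 0,
            }
        )
    return pd.DataFrame(rows)


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_2x2(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher's exact test built from log-factorials.

    All tables with the observed margins are enumerated; the two-sided
    p-value sums the hypergeometric probabilities of tables at most as
    probable as the observed one (minimum-likelihood method, with a 1e-12
    relative tolerance on the comparison).  The odds ratio is the sample
    ``(a*d)/(b*c)`` with zero-cell results of ``inf`` (b*c == 0) or 0
    reported as is.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_p(k: int) -> float:
        return _log_binom(r1, k) + _log_binom(r2, c1 - k) - _log_binom(n, c1)

    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    lp_obs = log_p(a)
    total = 0.0
    for k in range(k_min, k_max + 1):
        lp = log_p(k)
        if lp <= lp_obs + 1e-12 * abs(lp_obs) + 1e-12:
            total += math.exp(lp)
    p = min(total, 1.0)
    if 1.0 - p < 1e-12:  # all tables included: exactly 1 up to float error
        p = 1.0
    if b * c == 0:
        orat = math.inf if a * d > 0 else math.nan
    else:
        orat = (a * d) / (b * c)
    return FisherResult(p_two_sided=p, odds_ratio=orat)


# ---------------------------------------------------------------------- #
# annotation TSV
# ---------------------------------------------------------------------- #
_ANN_COLUMNS = [
    "clade_id",
    "jump_index",
    "side",
    "host_status",
    "marine",
    "oxygen_class",
    "source_note",
]


def read_annotation_table(path) -> dict[tuple[str, int], EcologyAnnotation]:
    """Read per-jump annotations from the two-row-per-jump TSV layout
    (one ``affected`` and one ``sister`` row per (clade_id, jump_index))."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    missing = [c for c in _ANN_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise GCJumpError(f"annotation TSV missing columns {missing}")
    out: dict[tuple[str, int], EcologyAnnotation] = {}
    for (clade, idx), grp in df.groupby(["clade_id", "jump_index"]):
        sides = dict(zip(grp["side"], grp.to_dict("records")))
        if set(sides) != {"affected", "sister"}:
            raise GCJumpError(
                f"jump ({clade}, {idx}) needs exactly one 'affected' and one "
                "'sister' row"
            )
        aff, sis = sides["affected"], sides["sister"]
        out[(str(clade), int(idx))] = EcologyAnnotation(
            host_status_affected=aff["host_status"],
            host_status_sister=sis["host_status"],
            marine=str(aff["marine"]).lower() in ("1", "true", "yes"),
            oxygen_affected=aff["oxygen_class"],
            oxygen_sister=sis["oxygen_class"],
        )
    return out


def write_annotation_table(
    annotations: dict[tuple[str, int], EcologyAnnotation], path
) -> None:
    rows = []
    for (clade, idx), ann in annotations.items():
        rows.append(
            {
                "clade_id": clade,
                "jump_index": idx,
                "side": "affected",
                "host_status": ann.host_status_affected,
                "marine": str(ann.marine).lower(),
                "oxygen_class": ann.oxygen_affected,
                "source_note": "",
            }
        )
        rows.append(
            {
                "clade_id": clade,
                "jump_index": idx,
                "side": "sister",
                "host_status": ann.host_status_sister,
                "marine": str(ann.marine).lower(),
                "oxygen_class": ann.oxygen_sister,
                "source_note": "",
            }
        )
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)
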