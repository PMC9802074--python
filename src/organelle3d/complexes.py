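"""Alone / binary / ternary complex classification.

Each chloroplast, peroxisome and mitochondrion is categorized by the *set
of other classes* it touches: Alone (no inter-class proximity), a binary
category per partner class, or the ternary category when both other
classes are present. Any proximity site with at least one overlap voxel
counts; same-class contacts are ignored. Because one organelle can touch
several partners of the same class, the fractions of reciprocal categories
need not be symmetric across classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .contact import ContactTable
from .io import CONTACT_CLASSES

_SHORT = {"chloroplast": "Chl", "peroxisome": "Per", "mitochondrion": "Mit"}


def category_name(own_class: str, partner_classes: frozenset[str] | set[str]) -> str:
    """Human-readable category, e.g. ``"Alone"``, ``"with Mit"``,
    ``"with Per and Mit"`` (partner order fixed per class)."""
    others = [c for c in CONTACT_CLASSES if c != own_class]
    present = [c for c in others if c in partner_classes]
    if not present:
        return "Alone"
    return "with " + " and ".join(_SHORT[c] for c in present)


def categories_for(own_class: str) -> list[str]:
    """The four categories of one class, in display order."""
    a, b = [c for c in CONTACT_CLASSES if c != own_class]
    return [
        "Alone",
        category_name(own_class, {a}),
        category_name(own_class, {b}),
        category_name(own_class, {a, b}),
    ]


@dataclass(frozen=True)
class ComplexAssignment:
    """Partner-class category of one organelle."""

    label: int
    organelle_class: str
    partner_classes: frozenset[str]
    category: str
    cell_id: str = ""
    condition: str | None = None


def classify(table: ContactTable) -> list[ComplexAssignment]:
    """Categorize every contact-class organelle of one cell.

    Pure function of the contact table's partner sets: idempotent and
    independent of site ordering. Organelles without sites are ``Alone``.
    """
    out = []
    for lbl in sorted(table.instance_classes):
        cls = table.instance_classes[lbl]
        partners = frozenset(
            c for c in table.partner_classes(lbl) if c != cls
        )
        out.append(
            ComplexAssignment(
                label=lbl,
                organelle_class=cls,
                partner_classes=partners,
                category=category_name(cls, partners),
                cell_id=table.cell_id,
                condition=table.condition,
            )
        )
    return out


def assignments_frame(assignments: list[ComplexAssignment]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": a.cell_id,
            "condition": a.condition,
            "label": a.label,
            "organelle_class": a.organelle_class,
            "partner_classes": "+".join(sorted(a.partner_classes)),
            "category": a.category,
        }
        for a in assignments
    ]
    cols = ["cell_id", "condition", "label", "organelle_class",
            "partner_classes", "category"]
    return pd.DataFrame(rows, columns=cols)


def population_fractions(assignments: list[ComplexAssignment]) -> pd.DataFrame:
    """Per condition x class x category counts and percentages.

    Organelles are pooled across all cells of a condition (matching how
    per-instance population percentages are normally reported), so each
    class's percentages sum to 100 within a condition. Conditions with no
    instances of a class yield no rows (fractions undefined).
    """
    rows = []
    conditions = sorted({a.condition for a in assignments}, key=str)
    for cond in conditions:
        for cls in CONTACT_CLASSES:
            sub = [a for a in assignments
                   if a.condition == cond and a.organelle_class == cls]
            n = len(sub)
            if n == 0:
                continue
            for cat in categories_for(cls):
                count = sum(1 for a in sub if a.category == cat)
                rows.append(
                    {
                        "condition": cond,
                        "organelle_class": cls,
                        "category": cat,
                        "count": count,
                        "n_total": n,
                        "percent": 100.0 * count / n,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["condition", "organelle_class", "category", "count",
                 "n_total", "percent"],
    )


def alone_vs_engaged_counts(fractions: pd.DataFrame, organelle_class: str
                            ) -> dict[str, tuple[int, int]]:
    """Per condition: (alone, engaged) counts for one class — the 2x2
    layout tested with Fisher's exact test."""
    out = {}
    sub = fractions[fractions["organelle_class"] == organelle_class]
    for cond, grp in sub.groupby("condition"):
        alone = int(grp.loc[grp["category"] == "Alone", "count"].sum())
        total = int(grp["count"].sum())
        out[cond] = (alone, total - alone)
    return out
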