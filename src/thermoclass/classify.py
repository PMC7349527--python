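"""The 15-class expression-profile scheme and cross-genotype concordance.

Each gene's significance-and-sign pattern over the three temperature
contrasts (39v25, 45v25, 45v39; each up/down/ns) maps to one of 15 classes
per genotype.  The 39v25 status fixes the block: up -> classes 1-5,
down -> 6-10, ns -> 11-15; within a block the 45v25 and 45v39 statuses
discriminate.  Three anchor cases pin the numbering: classes 1-3 are up at
both 39 and 45 degC, class 7 is down at 39 degC only, class 13 shows no
alteration at all.  The full 27-triple table is a package convention (the
published material does not print it) held in one editable mapping.

Concordance across genotypes: level 1 when the class is identical in every
genotype; level 2 when it is not, but the 39v25 statuses (or the 45v25
statuses) agree in every genotype.  Direction tags (common-up/down at 39 or
45 degC) accumulate level-1 and level-2 members per tag; one gene may carry
both a 39 and a 45 tag, but never counts in both levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

Status = str  # "up" | "down" | "ns"
STATUSES = ("up", "down", "ns")

#: canonical triple -> class table; '*' entries are expanded below
_CLASS_RULES: dict[tuple[str, str, str], int] = {}


def _expand(rule: tuple[str, str, str], cls: int) -> None:
    opts = [(s,) if s != "*" else STATUSES for s in rule]
    for a in opts[0]:
        for b in opts[1]:
            for c in opts[2]:
                _CLASS_RULES[(a, b, c)] = cls


# up block (upregulated at 39 degC)
_expand(("up", "up", "up"), 1)
_expand(("up", "up", "ns"), 2)
_expand(("up", "up", "down"), 3)
_expand(("up", "ns", "*"), 4)
_expand(("up", "down", "*"), 5)
# down block (downregulated at 39 degC)
_expand(("down", "down", "down"), 6)
_expand(("down", "ns", "*"), 7)
_expand(("down", "down", "ns"), 8)
_expand(("down", "down", "up"), 9)
_expand(("down", "up", "*"), 10)
# ns block (no 39v25 change)
_expand(("ns", "up", "*"), 11)
_expand(("ns", "ns", "up"), 12)
_expand(("ns", "ns", "ns"), 13)
_expand(("ns", "ns", "down"), 14)
_expand(("ns", "down", "*"), 15)

CLASS_TABLE: dict[tuple[str, str, str], int] = dict(_CLASS_RULES)
assert len(CLASS_TABLE) == 27


def assign_class(triple: tuple[str, str, str]) -> int:
    """Map a (39v25, 45v25, 45v39) status triple to its class 1..15."""
    if len(triple) != 3 or any(s not in STATUSES for s in triple):
        raise ValueError(f"incomplete or invalid status triple: {triple!r}")
    return CLASS_TABLE[tuple(triple)]


def classify_genotype(contrasts: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Class assignment per gene for one genotype from its three contrasts.

    ``contrasts`` maps '39v25'/'45v25'/'45v39' to diffexp result frames.
    Genes untested in any contrast are excluded (reported via the
    ``tested`` column of the result: only tested genes appear).
    Columns: class, status_39v25, status_45v25, status_45v39.
    """
    needed = ("39v25", "45v25", "45v39")
    missing = [k for k in needed if k not in contrasts]
    if missing:
        raise ValueError(f"missing contrasts: {missing}")
    s = {k: contrasts[k]["status"] for k in needed}
    tested = contrasts["39v25"]["tested"]
    for k in needed[1:]:
        tested = tested & contrasts[k]["tested"]
    idx = tested[tested].index
    df = pd.DataFrame(
        {
            "status_39v25": s["39v25"].loc[idx],
            "status_45v25": s["45v25"].loc[idx],
            "status_45v39": s["45v39"].loc[idx],
        }
    )
    df["class"] = [
        CLASS_TABLE[t]
        for t in zip(df["status_39v25"], df["status_45v25"], df["status_45v39"])
    ]
    return df[["class", "status_39v25", "status_45v25", "status_45v39"]]


TAGS = ("common_up_39", "common_down_39", "common_up_45", "common_down_45")


@dataclass
class ConcordanceResult:
    """Per-gene concordance levels and direction tags, plus exclusions."""

    records: pd.DataFrame  # index gene; columns level + TAGS
    excluded: pd.DataFrame  # gene, reason


def concordance(assignments: dict[str, pd.DataFrame]) -> ConcordanceResult:
    """Cross-genotype concordance from per-genotype class assignments.

    Level 1: the full status triple (hence the class) identical in every
    genotype.  Level 2: not level 1, but all genotypes share the 39v25
    status or all share the 45v25 status.
    Tags mark shared up/down statuses (level-1 genes tag through their
    common statuses too).  Genes missing an assignment in any genotype are
    excluded with a reason.
    """
    genotypes = list(assignments)
    if not genotypes:
        raise ValueError("no assignments given")
    common = None
    for g in genotypes:
        idx = assignments[g].index
        common = idx if common is None else common.intersection(idx)
    all_genes = pd.Index(sorted(set().union(*(set(assignments[g].index) for g in genotypes))))
    dropped = all_genes.difference(common)
    excluded = pd.DataFrame(
        {"gene_id": dropped, "reason": "missing assignment in at least one genotype"}
    )

    s39 = pd.DataFrame({g: assignments[g]["status_39v25"].loc[common] for g in genotypes})
    s45 = pd.DataFrame({g: assignments[g]["status_45v25"].loc[common] for g in genotypes})
    s4539 = pd.DataFrame({g: assignments[g]["status_45v39"].loc[common] for g in genotypes})

    # level 1 demands the full profile identical, not merely the class label:
    # classes absorbing a free third status would otherwise conflate profiles
    level1 = (
        (s39.nunique(axis=1) == 1)
        & (s45.nunique(axis=1) == 1)
        & (s4539.nunique(axis=1) == 1)
    )
    agree39 = s39.nunique(axis=1) == 1
    agree45 = s45.nunique(axis=1) == 1
    level2 = ~level1 & (agree39 | agree45)
    level = pd.Series("none", index=common)
    level[level2] = "2"
    level[level1] = "1"

    first39 = s39[genotypes[0]]
    first45 = s45[genotypes[0]]
    rec = pd.DataFrame({"level": level})
    rec["common_up_39"] = (level != "none") & agree39 & (first39 == "up")
    rec["common_down_39"] = (level != "none") & agree39 & (first39 == "down")
    rec["common_up_45"] = (level != "none") & agree45 & (first45 == "up")
    rec["common_down_45"] = (level != "none") & agree45 & (first45 == "down")
    return ConcordanceResult(records=rec, excluded=excluded)


def common_sets(result: ConcordanceResult) -> pd.DataFrame:
    """Accumulated common up/down gene counts per direction tag.

    One row per tag with level-1 members, level-2 members and the
    accumulated total (level1 + level2); gene lists are ';'-joined.
    """
    rec = result.records
    rows = []
    for tag in TAGS:
        l1 = rec.index[(rec["level"] == "1") & rec[tag]]
        l2 = rec.index[(rec["level"] == "2") & rec[tag]]
        rows.append(
            {
                "tag": tag,
                "level1": len(l1),
                "level2": len(l2),
                "total": len(l1) + len(l2),
                "level1_genes": ";".join(l1),
                "level2_genes": ";".join(l2),
            }
        )
    return pd.DataFrame(rows).set_index("tag")


def class_level_summary(assignments: dict[str, pd.DataFrame],
                        result: ConcordanceResult) -> pd.DataFrame:
    """Class x level count table (the per-class breakdown of concordance)."""
    genotypes = list(assignments)
    rec = result.records
    first = assignments[genotypes[0]]["class"].reindex(rec.index)
    rows = []
    for cls in range(1, 16):
        in_cls = first == cls
        rows.append(
            {
                "class": cls,
                "level1": int(((rec["level"] == "1") & in_cls).sum()),
                # level-2/none genes have no single cross-genotype class;
                # they are counted under the first genotype's class
                "level2": int(((rec["level"] == "2") & in_cls).sum()),
                "none": int(((rec["level"] == "none") & in_cls).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("class")
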