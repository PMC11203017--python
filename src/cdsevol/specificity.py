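"""Species-specific gene calling and annotation set logic.

A gene is called species-specific when it has protein-domain evidence
(a Pfam or InterPro hit) but no NR annotation and no homolog passing the
ortholog filters in any comparator species.  Specific genes are grouped
into orthogroups as connected components of the within-species paralog
graph (singletons form their own group), so both gene-level and
group-level counts are available.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import pandas as pd

from .homology import PairSet

ANNOTATION_COLUMNS = ["gene_id", "nr_hit", "pfam_hit", "interpro_hit"]


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    for col in ("nr_hit", "pfam_hit", "interpro_hit"):
        df[col] = df[col].astype(int).astype(bool)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate annotation row for gene {dup!r}")
    return df


def read_go_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "go_id"} - set(df.columns)
    if missing:
        raise ValueError(f"GO map missing columns {sorted(missing)}")
    return df


def _comparator_hits(pair_sets: Mapping[str, PairSet | pd.DataFrame]) -> set[str]:
    """Focal gene ids that have an ortholog pair in any comparator."""
    hit: set[str] = set()
    for ps in pair_sets.values():
        df = ps.to_frame() if isinstance(ps, PairSet) else ps
        hit.update(df["id_a"].astype(str))
    return hit


def call_specific(
    annotations: pd.DataFrame,
    ortholog_pairs: Mapping[str, PairSet | pd.DataFrame],
    gene_ids: Optional[list[str]] = None,
    paralog_pairs: Optional[PairSet | pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-gene specificity calls plus orthogroup ids for the specific genes.

    ``gene_ids`` (default: annotation table order) must all have annotation
    rows; a missing row is an error.
    """
    ann = annotations.set_index("gene_id")
    if gene_ids is None:
        gene_ids = list(ann.index)
    else:
        missing = [g for g in gene_ids if g not in ann.index]
        if missing:
            raise ValueError(f"no annotation row for gene {missing[0]!r}")

    has_comparator = _comparator_hits(ortholog_pairs)
    rows = []
    for g in gene_ids:
        r = ann.loc[g]
        domain = bool(r["pfam_hit"]) or bool(r["interpro_hit"])
        no_nr = not bool(r["nr_hit"])
        absent = g not in has_comparator
        is_specific = domain and no_nr and absent
        evidence = []
        if domain:
            evidence.append("domain_hit")
        if no_nr:
            evidence.append("no_nr_hit")
        if absent:
            evidence.append("no_comparator_ortholog")
        rows.append(
            {
                "gene_id": g,
                "is_specific": is_specific,
                "evidence": ";".join(evidence),
            }
        )
    calls = pd.DataFrame(rows)

    specific = set(calls.loc[calls["is_specific"], "gene_id"])
    graph = nx.Graph()
    graph.add_nodes_from(specific)
    if paralog_pairs is not None:
        pdf = (
            paralog_pairs.to_frame()
            if isinstance(paralog_pairs, PairSet)
            else paralog_pairs
        )
        for row in pdf.itertuples(index=False):
            if row.id_a in specific and row.id_b in specific:
                graph.add_edge(row.id_a, row.id_b)
    group_of: dict[str, str] = {}
    for i, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]), start=1
    ):
        for g in comp:
            group_of[g] = f"SSG{i:04d}"
    calls["orthogroup_id"] = [group_of.get(g, "") for g in calls["gene_id"]]
    return calls


def specific_group_count(calls: pd.DataFrame) -> int:
    groups = calls.loc[calls["is_specific"], "orthogroup_id"]
    return groups.nunique()


VENN_REGIONS = [
    "nr_only",
    "pfam_only",
    "interpro_only",
    "nr_pfam",
    "nr_interpro",
    "pfam_interpro",
    "nr_pfam_interpro",
    "none",
]


def venn_counts(annotations: pd.DataFrame) -> dict[str, int]:
    """Counts of the 7 NR/Pfam/InterPro regions plus the none-of-three count."""
    counts = dict.fromkeys(VENN_REGIONS, 0)
    for row in annotations.itertuples(index=False):
        key = (bool(row.nr_hit), bool(row.pfam_hit), bool(row.interpro_hit))
        name = {
            (True, False, False): "nr_only",
            (False, True, False): "pfam_only",
            (False, False, True): "interpro_only",
            (True, True, False): "nr_pfam",
            (True, False, True): "nr_interpro",
            (False, True, True): "pfam_interpro",
            (True, True, True): "nr_pfam_interpro",
            (False, False, False): "none",
        }[key]
        counts[name] += 1
    return counts


def domain_counts(
    domain_table: pd.DataFrame, gene_list: Optional[set[str]] = None
) -> pd.DataFrame:
    """Tally domain names among a gene list (semicolon-separated ``domains`` column)."""
    if "domains" not in domain_table.columns:
        raise ValueError("domain table needs a 'domains' column")
    tally: dict[str, int] = {}
    for row in domain_table.itertuples(index=False):
        if gene_list is not None and row.gene_id not in gene_list:
            continue
        if not isinstance(row.domains, str) or not row.domains:
            continue
        for d in row.domains.split(";"):
            d = d.strip()
            if d:
                tally[d] = tally.get(d, 0) + 1
    return (
        pd.DataFrame(sorted(tally.items()), columns=["domain", "count"])
        .sort_values(["count", "domain"], ascending=[False, True])
        .reset_index(drop=True)
    )


def write_specificity(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    out["is_specific"] = out["is_specific"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def write_venn(counts: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        [{"region": k, "count": counts[k]} for k in VENN_REGIONS]
    ).to_csv(path, sep="\t", index=False)
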