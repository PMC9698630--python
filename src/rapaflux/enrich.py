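"""Pathway over-representation and topological impact for module metabolites.

Each module (or treatment-wise union of modules) is mapped to compound IDs
and tested against every pathway of a compound-set database:

* **over-representation**: upper-tail hypergeometric probability of drawing
  at least ``k`` pathway compounds in ``n`` query compounds from a background
  of ``N`` compounds containing ``M`` pathway members;
* **impact**: the summed relative betweenness centrality of the hit
  compounds within the pathway's compound graph, normalized by the summed
  centrality of all pathway nodes -- hits at topological bottlenecks score
  high, peripheral hits score 0.

A pathway "passes" the screen when p < 0.05 and it has at least 3 hits (no
multiple-testing correction), the screening rule used for the elicitor
modules.  A compact hand-curated database (12 pathways around central
carbon, amino-acid and cofactor metabolism) is bundled for the default
pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .exceptions import ParameterError, ValidationError
from .modnet import ModuleSet

#: Compound universe of the bundled database's mapping space (a KEGG-scale
#: count); the default over-representation background.
BUNDLED_BACKGROUND_SIZE = 1600


@dataclass
class PathwayDB:
    """Named compound sets with per-pathway graphs for impact scoring."""

    pathways: dict[str, set[str]]            # name -> compound IDs
    graphs: dict[str, nx.Graph] = field(default_factory=dict)
    background_size: int = BUNDLED_BACKGROUND_SIZE
    descriptions: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for name, graph in self.graphs.items():
            if name not in self.pathways:
                raise ValidationError(f"graph for unknown pathway '{name}'")
            extra = set(graph.nodes) - self.pathways[name]
            if extra:
                raise ValidationError(
                    f"pathway '{name}' graph has nodes outside its compound "
                    f"set: {sorted(extra)}")
        largest = max((len(c) for c in self.pathways.values()), default=0)
        if self.background_size < largest:
            raise ValidationError("background_size smaller than a pathway")


def load_pathway_db(sets_path, edges_path=None,
                    background_size: int = BUNDLED_BACKGROUND_SIZE) -> PathwayDB:
    """Read a GMT-style compound-set TSV plus an optional edge-list TSV."""
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(sets_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"malformed pathway line: {line[:60]!r}")
            name, desc, compounds = parts[0], parts[1], parts[2:]
            pathways[name] = set(c for c in compounds if c)
            descriptions[name] = desc
    graphs: dict[str, nx.Graph] = {}
    if edges_path is not None:
        edges = pd.read_csv(edges_path, sep="\t")
        for name, grp in edges.groupby("pathway"):
            g = nx.Graph()
            g.add_nodes_from(sorted(pathways.get(str(name), set())))
            g.add_edges_from(zip(grp["compound_a"], grp["compound_b"]))
            graphs[str(name)] = g
    for name in pathways:
        graphs.setdefault(name, nx.Graph())
        if graphs[name].number_of_nodes() == 0:
            graphs[name].add_nodes_from(sorted(pathways[name]))
    db = PathwayDB(pathways=pathways, graphs=graphs,
                   background_size=background_size, descriptions=descriptions)
    db.validate()
    return db


def load_bundled_db() -> PathwayDB:
    """The hand-curated 12-pathway database shipped with the package."""
    data = resources.files("rapaflux") / "data"
    return load_pathway_db(str(data / "pathways.tsv"),
                           str(data / "pathway_edges.tsv"))


def load_compound_map(path=None) -> dict[str, str]:
    """Metabolite-name -> compound-ID table (bundled table by default)."""
    if path is None:
        path = str(resources.files("rapaflux") / "data" / "compound_map.tsv")
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["metabolite"], df["compound_id"]))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def ora_pvalue(k: int, M: int, n: int, N: int) -> float:
    """Hypergeometric upper tail P(X >= k): population N, successes M, draws n."""
    if not (0 <= k <= min(M, n) <= N and M <= N and n <= N):
        raise ParameterError(
            f"inconsistent counts k={k}, M={M}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, M, n))


def pathway_impact(hit_compounds, graph: nx.Graph) -> float:
    """Share of the pathway's relative betweenness carried by the hits.

    Betweenness is computed on the undirected graph with endpoint pairs
    excluded (the standard definition) and normalized; unmatched hits
    contribute 0.  An empty graph or an all-leaf pathway has impact 0.
    """
    if graph.number_of_nodes() == 0:
        warnings.warn("empty pathway graph; impact set to 0")
        return 0.0
    bc = nx.betweenness_centrality(graph, normalized=True)
    total = sum(bc.values())
    if total == 0:
        return 1.0 if set(hit_compounds) >= set(graph.nodes) and bc else 0.0
    hit_sum = sum(bc.get(c, 0.0) for c in sorted(set(hit_compounds)))
    return float(hit_sum / total)


# ---------------------------------------------------------------------------
# the module screen
# ---------------------------------------------------------------------------

def map_to_compounds(metabolites, mapping: dict[str, str]) -> list[str]:
    """Map metabolite names into compound IDs; unmapped names are dropped."""
    mapped, missing = [], []
    for m in metabolites:
        if m in mapping:
            mapped.append(mapping[m])
        else:
            missing.append(m)
    if missing:
        warnings.warn(f"{len(missing)} metabolites had no compound mapping "
                      f"and are excluded: {sorted(missing)[:5]}...")
    return sorted(set(mapped))


def enrich_compounds(compounds, db: PathwayDB, query_name: str = "query",
                     p_cut: float = 0.05, min_hits: int = 3,
                     background: int | None = None) -> pd.DataFrame:
    """Score one compound query against every pathway of the database."""
    N = background if background is not None else db.background_size
    n = len(set(compounds))
    rows = []
    for name in sorted(db.pathways):
        members = db.pathways[name]
        M = len(members)
        hits = sorted(set(compounds) & members)
        k = len(hits)
        p = ora_pvalue(k, M, min(n, N), N)
        impact = pathway_impact(hits, db.graphs[name]) if k else 0.0
        rows.append({
            "query": query_name, "pathway": name,
            "description": db.descriptions.get(name, name),
            "hits": k, "pathway_size": M, "query_size": n, "p_value": p,
            "impact": impact,
            "passed": bool(p < p_cut and k >= min_hits),
            "hit_compounds": ";".join(hits),
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["p_value", "pathway"], kind="mergesort").reset_index(drop=True)


def enrich_modules(modules: ModuleSet, db: PathwayDB,
                   mapping: dict[str, str] | None = None,
                   p_cut: float = 0.05, min_hits: int = 3,
                   background: int | None = None,
                   combine_by_trait: bool = True) -> pd.DataFrame:
    """Pathway screen of the selected modules (p < 0.05 and >= 3 hits pass).

    With ``combine_by_trait`` the modules associated with the same treatment
    are pooled into one query per treatment (the way multi-module treatments
    are analyzed); otherwise each module is screened separately.  Modules
    whose members have no compound mapping at all are skipped with a warning.
    """
    mapping = mapping if mapping is not None else load_compound_map()
    queries: dict[str, list[str]] = {}
    if combine_by_trait and modules.selected:
        groups: dict[str, list[str]] = {}
        for module, trait in sorted(modules.selected.items()):
            groups.setdefault(trait, []).append(module)
        for trait, mods in sorted(groups.items()):
            mets: list[str] = []
            for module in mods:
                mets.extend(modules.members(module))
            queries[f"{trait} ({'+'.join(mods)})"] = mets
    else:
        for module in modules.module_labels():
            queries[module] = modules.members(module)

    frames = []
    for qname, mets in queries.items():
        compounds = map_to_compounds(mets, mapping)
        if not compounds:
            warnings.warn(f"query '{qname}' has no mappable compounds; skipped")
            continue
        frames.append(enrich_compounds(compounds, db, query_name=qname,
                                       p_cut=p_cut, min_hits=min_hits,
                                       background=background))
    if not frames:
        return pd.DataFrame(columns=["query", "pathway", "description", "hits",
                                     "pathway_size", "query_size", "p_value",
                                     "impact", "passed", "hit_compounds"])
    return pd.concat(frames, ignore_index=True)
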