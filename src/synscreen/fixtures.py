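"""Deterministic synthetic fixtures: toy networks, ontologies and drug
panels, plus a hand-computed gold instance.

These generators exist to exercise every formula of the screen end to end
without external downloads. They are pure functions of (parameters, seed):
the same seed reproduces byte-identical files. The chemistry is a fixed
toy SMILES library and random typed feature points — deliberately
unrealistic, sized to make expected values computable by hand.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import DomainError
from .network import InteractionNetwork

#: Small fixed library of (canonical) toy SMILES strings.
TOY_SMILES = (
    "CCCCC",
    "CCCC",
    "C1CCCCC1",
    "c1ccccc1O",
    "CC(C)CC(=O)O",
    "CCN(CC)CC",
    "C1CC1CO",
    "c1ccncc1C",
    "CC(=O)Nc1ccccc1",
    "OCC(O)C(O)CO",
    "CC#CCCl",
    "C1=CC(=O)NC1",
)

SITE_ALPHABET = "ADHNPR"


@dataclass
class FixtureBundle:
    """Paths of one generated fixture set plus its expected-value ledger."""

    root: Path
    network: Path
    disease_genes: Path
    targets: Path
    smiles: Path
    sites: Path
    obo: Path
    annotations: Path
    config: Path
    manifest: Path
    manifest_data: dict = field(default_factory=dict)


def gen_ppi(n_nodes: int, model: str = "scale_free",
            edge_param: float = 2, seed: int = 0) -> InteractionNetwork:
    """Connected undirected toy network, deterministic per seed.

    ``scale_free`` grows a Barabasi-Albert graph with ``edge_param``
    attachments per node; ``random`` is Erdos-Renyi with edge probability
    ``edge_param``, made connected by chaining components.
    """
    if n_nodes < 4:
        raise DomainError(f"need n_nodes >= 4, got {n_nodes}")
    if model == "scale_free":
        m = max(1, int(edge_param))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    elif model == "random":
        g = nx.gnp_random_graph(n_nodes, float(edge_param), seed=seed)
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort()
        for prev, nxt in zip(comps, comps[1:]):
            g.add_edge(prev[0], nxt[0])
    else:
        raise DomainError(f"unknown network model {model!r}")
    if g.number_of_edges() == 0:
        raise DomainError("network parameters yield no edges")
    relabel = {i: f"G{i:04d}" for i in g.nodes}
    return InteractionNetwork(nx.relabel_nodes(g, relabel))


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    lines = ["# node_a\tnode_b"]
    for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
        lines.append(f"{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n")


def gen_go_corpus(depth: int, branching: int, genes: list[str],
                  seed: int = 0) -> tuple[str, str]:
    """Toy rooted tree ontology and a gene-annotation table.

    Returns (obo_text, annotations_tsv_text). Terms form a complete tree
    of the given depth and branching factor; every term receives one
    direct filler annotation, so cumulative frequencies strictly decrease
    with depth. Each input gene is annotated to one seeded-random term.
    """
    if depth < 2:
        raise DomainError(f"need depth >= 2, got {depth}")
    if branching < 1:
        raise DomainError(f"need branching >= 1, got {branching}")
    rng = np.random.default_rng(seed)
    terms: list[str] = []
    parent: dict[str, str | None] = {}
    level_of: dict[str, int] = {}

    def tid(k: int) -> str:
        return f"TOY:{k:07d}"

    counter = 0
    root = tid(counter)
    counter += 1
    terms.append(root)
    parent[root] = None
    level_of[root] = 0
    frontier = [root]
    for level in range(1, depth):
        nxt = []
        for p in frontier:
            for _ in range(branching):
                t = tid(counter)
                counter += 1
                terms.append(t)
                parent[t] = p
                level_of[t] = level
                nxt.append(t)
        frontier = nxt

    stanzas = ["format-version: 1.2", "ontology: toy", ""]
    for t in terms:
        stanzas.append("[Term]")
        stanzas.append(f"id: {t}")
        stanzas.append(f"name: toy term {t}")
        if parent[t] is not None:
            stanzas.append(f"is_a: {parent[t]}")
        stanzas.append("")
    obo_text = "\n".join(stanzas)

    rows = ["# gene\tterm"]
    # one filler annotation per term keeps every term informative and
    # makes Freq(parent) > Freq(child) strictly
    for i, t in enumerate(terms):
        rows.append(f"FILLER{i:04d}\t{t}")
    for g in genes:
        t = terms[int(rng.integers(0, len(terms)))]
        rows.append(f"{g}\t{t}")
    return obo_text, "\n".join(rows) + "\n"


def gen_drug_panel(n_drugs: int, net: InteractionNetwork, seed: int = 0,
                   planted_synergist: bool = False,
                   reference_id: str = "LEF", targets_per_drug: int = 3,
                   sites_per_drug: int = 3
                   ) -> tuple[str, str, str, list[str]]:
    """Seeded drug panel: reference + decoys (+ optional planted winner).

    Returns (smiles_text, targets_tsv, sites_tsv, drug_ids). The
    reference drug targets hub nodes of the network; decoys draw targets
    uniformly. With ``planted_synergist`` an extra drug ``PLANTED``
    copies the reference's targets and SMILES and jitters its
    pharmacophore sites by ~0.05 angstrom, so it should dominate every
    score axis.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(net.graph.nodes)
    by_degree = sorted(nodes, key=lambda v: (-net.graph.degree(v), v))
    hubs = by_degree[:max(targets_per_drug * 2, 6)]

    drug_ids = [reference_id] + [f"DRUG{i:02d}" for i in range(n_drugs)]
    smiles_rows: list[str] = []
    target_rows = ["# drug_id\ttarget_id"]
    site_rows = ["drug_id\tsite_type\tx\ty\tz"]

    def add_sites(drug: str, coords: np.ndarray, types: list[str]) -> None:
        for (x, y, z), st in zip(coords, types):
            site_rows.append(f"{drug}\t{st}\t{x:.4f}\t{y:.4f}\t{z:.4f}")

    ref_targets = [hubs[i] for i in
                   rng.choice(len(hubs), size=targets_per_drug,
                              replace=False)]
    ref_smiles = TOY_SMILES[0]
    ref_coords = rng.uniform(-3, 3, size=(sites_per_drug, 3))
    ref_types = [SITE_ALPHABET[i] for i in
                 rng.integers(0, len(SITE_ALPHABET), size=sites_per_drug)]

    for drug in drug_ids:
        if drug == reference_id:
            targets, smi = ref_targets, ref_smiles
            coords, types = ref_coords, ref_types
        else:
            targets = [nodes[i] for i in
                       rng.choice(len(nodes), size=targets_per_drug,
                                  replace=False)]
            smi = TOY_SMILES[1 + int(rng.integers(0, len(TOY_SMILES) - 1))]
            coords = rng.uniform(-3, 3, size=(sites_per_drug, 3))
            types = [SITE_ALPHABET[i] for i in
                     rng.integers(0, len(SITE_ALPHABET),
                                  size=sites_per_drug)]
        smiles_rows.append(f"{smi}\t{drug}")
        for t in targets:
            target_rows.append(f"{drug}\t{t}")
        add_sites(drug, coords, types)

    if planted_synergist:
        drug_ids.append("PLANTED")
        smiles_rows.append(f"{ref_smiles}\tPLANTED")
        for t in ref_targets:
            target_rows.append(f"PLANTED\t{t}")
        jitter = rng.normal(0.0, 0.05, size=ref_coords.shape)
        add_sites("PLANTED", ref_coords + jitter, ref_types)

    return ("\n".join(smiles_rows) + "\n",
            "\n".join(target_rows) + "\n",
            "\n".join(site_rows) + "\n",
            drug_ids)


def _disease_ball(net: InteractionNetwork, size: int) -> list[str]:
    """Deterministic connected node set: BFS ball around the top hub."""
    g = net.graph
    start = max(sorted(g.nodes), key=lambda v: (g.degree(v), v))
    order = [start]
    seen = {start}
    frontier = [start]
    while frontier and len(order) < size:
        nxt = []
        for v in frontier:
            for u in sorted(g.neighbors(v)):
                if u not in seen:
                    seen.add(u)
                    order.append(u)
                    nxt.append(u)
                    if len(order) >= size:
                        break
            if len(order) >= size:
                break
        frontier = nxt
    return sorted(order)


def gen_fixture_bundle(out_dir: str | Path, seed: int,
                       planted_synergist: bool = False,
                       n_nodes: int = 60, n_drugs: int = 8,
                       reference_id: str = "LEF") -> FixtureBundle:
    """Generate a complete fixture set under ``out_dir``.

    The network is scale-free; disease genes are a BFS ball around the
    main hub (half the nodes), so the induced disease subnetwork is
    connected; the annotation corpus covers all network nodes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = gen_ppi(n_nodes, "scale_free", 2, seed=seed)
    disease = _disease_ball(net, n_nodes // 2)
    obo_text, ann_text = gen_go_corpus(depth=4, branching=3,
                                       genes=sorted(net.graph.nodes),
                                       seed=seed + 1)
    smi_text, tgt_text, site_text, drug_ids = gen_drug_panel(
        n_drugs, net, seed=seed + 2, planted_synergist=planted_synergist,
        reference_id=reference_id)

    paths = FixtureBundle(
        root=out,
        network=out / "network.tsv",
        disease_genes=out / "disease_genes.txt",
        targets=out / "targets.tsv",
        smiles=out / "drugs.smi",
        sites=out / "sites.tsv",
        obo=out / "toy.obo",
        annotations=out / "annotations.tsv",
        config=out / "config.yaml",
        manifest=out / "manifest.json",
    )
    write_edge_list(net, paths.network)
    paths.disease_genes.write_text("\n".join(disease) + "\n")
    paths.targets.write_text(tgt_text)
    paths.smiles.write_text(smi_text)
    paths.sites.write_text(site_text)
    paths.obo.write_text(obo_text)
    paths.annotations.write_text(ann_text)
    paths.config.write_text("# defaults\nseed: %d\n" % seed)
    manifest = {
        "seed": seed,
        "planted_synergist": planted_synergist,
        "reference": reference_id,
        "drugs": drug_ids,
        "n_nodes": net.n_nodes(),
        "n_edges": net.n_edges(),
    }
    paths.manifest.write_text(json.dumps(manifest, indent=2) + "\n")
    paths.manifest_data = manifest
    return paths


# ---------------------------------------------------------------------------
# gold instance: every expected value below is derivable by hand
# ---------------------------------------------------------------------------

#: Expected values of the gold instance and how each arises.
GOLD_EXPECTED = {
    # path A-B-C-D-E; REF targets {B}, CAND targets {D}; m = n = 1 and
    # D(B,{D}) = D(D,{B}) = 2, so S = 2 * exp(-2/1)
    "s_tnetwork": 2.0 * math.exp(-2.0),
    # Lin similarity of siblings X (p=1/4) and Y (p=1/8) through their
    # most informative common ancestor A (p=1/2):
    # 2*log2(1/2) / (log2(1/4) + log2(1/8)) = -2/-5 = 0.4
    "term_similarity": 0.4,
    # single ordered cross pair both ways: 2*0.4 / (2*1) = 0.4
    "s_function": 0.4,
    # LINGO q=4: "CCCCC" -> {CCCC: 2}, "CCCC" -> {CCCC: 1};
    # 1 - |2-1|/(2+1) = 2/3
    "s_2d": 2.0 / 3.0,
    # single same-type site pair at 1 angstrom, sigma 1: exp(-1)
    "s_3d": math.exp(-1.0),
    "s_similarity": 2.0 / 3.0 + math.exp(-1.0),
}

_GOLD_OBO = """format-version: 1.2
ontology: toy

[Term]
id: TOY:0000001
name: root

[Term]
id: TOY:0000002
name: mid
is_a: TOY:0000001

[Term]
id: TOY:0000003
name: leaf X
is_a: TOY:0000002

[Term]
id: TOY:0000004
name: leaf Y
is_a: TOY:0000002
"""

# direct annotation counts: root 4, mid 1, X 2, Y 1
# cumulative: Y=1, X=2, mid=4, root=8 -> p = 1/8, 1/4, 1/2, 1
_GOLD_ANNOTATIONS = """# gene\tterm
F1\tTOY:0000001
F2\tTOY:0000001
F3\tTOY:0000001
F4\tTOY:0000001
F5\tTOY:0000002
B\tTOY:0000003
F6\tTOY:0000003
D\tTOY:0000004
"""

_GOLD_NETWORK = """# node_a\tnode_b
A\tB
B\tC
C\tD
D\tE
"""

_GOLD_SMILES = "CCCCC\tREF\nCCCC\tCAND\n"

_GOLD_SITES = """drug_id\tsite_type\tx\ty\tz
REF\tA\t0.0\t0.0\t0.0
CAND\tA\t1.0\t0.0\t0.0
"""


def gold_instance(out_dir: str | Path) -> FixtureBundle:
    """Write the hand-computed gold instance under ``out_dir``.

    A five-node path network A-B-C-D-E, a four-term toy ontology with
    annotation probabilities {1, 1/2, 1/4, 1/8}, two drugs (REF targeting
    B with SMILES CCCCC, CAND targeting D with SMILES CCCC) and a single
    same-type pharmacophore site pair one angstrom apart. The manifest
    carries every expected score with its derivation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = FixtureBundle(
        root=out,
        network=out / "network.tsv",
        disease_genes=out / "disease_genes.txt",
        targets=out / "targets.tsv",
        smiles=out / "drugs.smi",
        sites=out / "sites.tsv",
        obo=out / "toy.obo",
        annotations=out / "annotations.tsv",
        config=out / "config.yaml",
        manifest=out / "manifest.json",
    )
    paths.network.write_text(_GOLD_NETWORK)
    paths.disease_genes.write_text("A\nB\nC\nD\nE\n")
    paths.targets.write_text("# drug_id\ttarget_id\nREF\tB\nCAND\tD\n")
    paths.smiles.write_text(_GOLD_SMILES)
    paths.sites.write_text(_GOLD_SITES)
    paths.obo.write_text(_GOLD_OBO)
    paths.annotations.write_text(_GOLD_ANNOTATIONS)
    paths.config.write_text("# all defaults\n")
    manifest = {
        "reference": "REF",
        "candidate": "CAND",
        "expected": dict(GOLD_EXPECTED),
        "derivations": {
            "s_tnetwork": "m=n=1, D=2 both ways on the path -> 2*exp(-2)",
            "term_similarity": "Lin(X,Y) via MICA mid (p=1/2) -> 0.4",
            "s_function": "2*0.4/((1+1)(1+1-1)) = 0.4",
            "s_2d": "{CCCC:2} vs {CCCC:1} -> 1 - 1/3",
            "s_3d": "one A-A pair at 1 A, sigma=1 -> exp(-1)",
            "s_similarity": "s_2d + s_3d",
        },
    }
    paths.manifest.write_text(json.dumps(manifest, indent=2) + "\n")
    paths.manifest_data = manifest
    return paths
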