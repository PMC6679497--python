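"""Candidate assembly, normalization and diagonal ranking.

The screen scores every candidate drug against a fixed reference drug on
three axes — target-network synergy, functional (GO) synergy, and
structural (2D + 3D) similarity — min-max normalizes each axis across
candidates, and ranks by the projection of the normalized triple onto the
main diagonal of the unit cube:

    total = (x + y + z) / sqrt(3)

The winner is the candidate farthest from the origin along the diagonal.
Diagonal projection orders identically to the plain normalized sum; a
Euclidean-norm rule is available for comparison.

The public surface follows the model/results idiom: build a
:class:`SynergyScreen` from data (or files), call :meth:`SynergyScreen.fit`,
and read the ranked table, per-axis diagnostics and summary off the
returned :class:`ScreenResults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, gofunction, network, tnetwork
from .config import RunConfig, load_config
from .errors import (DomainError, InputIOError, SynscreenError,
                     UndefinedScoreError, warn)

logger = logging.getLogger(__name__)

#: Fixed column order of the ranked output table.
RANKED_COLUMNS = ["rank", "drug_id", "s_tnetwork", "s_function", "s_2d",
                  "s_3d", "s_similarity", "norm_x", "norm_y", "norm_z",
                  "total"]


@dataclass(frozen=True)
class DrugRecord:
    """One drug: identifier, targets, and optional structure data."""

    drug_id: str
    targets: tnetwork.TargetSet
    smiles: chem.SmilesString | None = None
    sites: chem.PharmacophoreSiteSet | None = None


def read_target_table(path: str | Path) -> dict[str, tnetwork.TargetSet]:
    """Read a long-format (drug_id, target_id) TSV into target sets."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["drug_id", "target_id"], dtype=str)
    except OSError as exc:
        raise InputIOError(f"cannot read target table {path}: {exc}") from exc
    df = df[df["drug_id"] != "drug_id"]  # tolerate a header line
    out: dict[str, list[str]] = {}
    for drug_id, target in df.itertuples(index=False):
        out.setdefault(drug_id, []).append(target)
    return {d: tnetwork.TargetSet(d, tuple(ts)) for d, ts in out.items()}


def _axis_tnetwork(ref: DrugRecord, cand: DrugRecord,
                   net: network.InteractionNetwork, cs: pd.DataFrame,
                   config: RunConfig) -> float:
    try:
        return tnetwork.s_tnetwork(ref.targets, cand.targets, net, cs,
                                   exponent_sign=config.exponent_sign)
    except UndefinedScoreError as exc:
        warn(f"{cand.drug_id}: target-network axis downgraded to 0 ({exc})",
             code="screen.axis_tnetwork_zero")
        return 0.0


def _axis_function(ref: DrugRecord, cand: DrugRecord,
                   corpus: gofunction.GOAnnotationCorpus | None,
                   config: RunConfig) -> float:
    if corpus is None:
        warn(f"{cand.drug_id}: no annotation corpus; function axis 0",
             code="screen.axis_function_zero")
        return 0.0
    try:
        return gofunction.s_function(ref.targets, cand.targets, corpus,
                                     aggregation=config.aggregation,
                                     mica_rule=config.mica_rule)
    except SynscreenError as exc:
        warn(f"{cand.drug_id}: function axis downgraded to 0 ({exc})",
             code="screen.axis_function_zero")
        return 0.0


def _axis_similarity(ref: DrugRecord, cand: DrugRecord,
                     config: RunConfig) -> tuple[float, float, float]:
    """Return (s_2d, s_3d, s_similarity) with per-part downgrades."""
    if ref.smiles is None or cand.smiles is None:
        warn(f"{cand.drug_id}: missing SMILES; 2D axis 0",
             code="screen.axis_2d_zero")
        s2d = 0.0
    else:
        s2d = chem.lingosim(chem.lingo_profile(ref.smiles, config.q),
                            chem.lingo_profile(cand.smiles, config.q))
    if ref.sites is None or cand.sites is None or not len(ref.sites) \
            or not len(cand.sites):
        if config.missing_3d == "skip_axis":
            return s2d, float("nan"), s2d
        warn(f"{cand.drug_id}: missing 3D site data; 3D part 0",
             code="screen.axis_3d_zero")
        s3d = 0.0
    else:
        s3d = chem.s_3d(ref.sites, cand.sites, sigma=config.sigma)
    return s2d, s3d, chem.s_similarity(s2d, s3d)


def assemble_scores(reference: DrugRecord, candidates: list[DrugRecord],
                    net: network.InteractionNetwork, cs: pd.DataFrame,
                    corpus: gofunction.GOAnnotationCorpus | None,
                    config: RunConfig | None = None) -> pd.DataFrame:
    """Raw score axes for every candidate against the reference.

    Per-axis failures (no mapped targets, missing annotations or
    structure data) downgrade that axis to 0 with a structured warning;
    a candidate is never silently dropped from the screen.
    """
    if not candidates:
        raise DomainError("candidate list is empty")
    config = config or RunConfig()
    rows = []
    for cand in candidates:
        s_tn = _axis_tnetwork(reference, cand, net, cs, config)
        s_fn = _axis_function(reference, cand, corpus, config)
        s2d, s3d, s_sim = _axis_similarity(reference, cand, config)
        rows.append({"drug_id": cand.drug_id, "s_tnetwork": s_tn,
                     "s_function": s_fn, "s_2d": s2d, "s_3d": s3d,
                     "s_similarity": s_sim})
    return pd.DataFrame(rows)


def _minmax(col: pd.Series) -> pd.Series:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return pd.Series(0.5, index=col.index)
    return (col - lo) / (hi - lo)


def normalize_and_rank(scores: pd.DataFrame,
                       total_rule: str = "diagonal") -> pd.DataFrame:
    """Min-max normalize the three axes and rank along the diagonal.

    A constant axis maps every candidate to 0.5 (neutral). Ties in the
    total break lexicographically by drug_id; ranks are 1..N with no
    gaps.
    """
    if scores.empty:
        raise DomainError("no score vectors to rank")
    if total_rule not in ("diagonal", "sum", "euclidean"):
        raise DomainError(f"total_rule {total_rule!r} not in "
                          "('diagonal', 'sum', 'euclidean')")
    df = scores.copy()
    df["norm_x"] = _minmax(df["s_tnetwork"])
    df["norm_y"] = _minmax(df["s_function"])
    df["norm_z"] = _minmax(df["s_similarity"])
    xyz = df[["norm_x", "norm_y", "norm_z"]]
    if total_rule == "diagonal":
        df["total"] = xyz.sum(axis=1) / math.sqrt(3.0)
    elif total_rule == "sum":
        df["total"] = xyz.sum(axis=1)
    else:
        df["total"] = np.sqrt((xyz ** 2).sum(axis=1))
    df = df.sort_values(["total", "drug_id"],
                        ascending=[False, True], kind="mergesort")
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)[RANKED_COLUMNS]


def write_ranked_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the ranked table as TSV, floats at 6 significant digits."""
    if df.empty:
        raise DomainError("refusing to write an empty ranked table")
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    except OSError as exc:
        raise InputIOError(f"cannot write ranked table {path}: {exc}") from exc


def read_ranked_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


class SynergyScreen:
    """Synergy screen of candidate drugs against a reference drug.

    Parameters
    ----------
    background
        The background PPI network.
    disease_genes
        Driver genes inducing the disease signaling subnetwork.
    drugs
        All drug records, including the reference.
    reference_id
        drug_id of the reference drug; every other drug is a candidate.
    corpus
        GO annotation corpus for the functional axis (None disables it).
    config
        Run configuration; defaults apply when None.

    Examples
    --------
    >>> screen = SynergyScreen(background, disease_genes, drugs, "LEF")
    >>> results = screen.fit()
    >>> results.table.head()
    """

    def __init__(self, background: network.InteractionNetwork,
                 disease_genes: network.GeneSet,
                 drugs: list[DrugRecord], reference_id: str,
                 corpus: gofunction.GOAnnotationCorpus | None = None,
                 config: RunConfig | None = None):
        self.background = background
        self.disease_genes = disease_genes
        self.config = config or RunConfig()
        by_id = {d.drug_id: d for d in drugs}
        if reference_id not in by_id:
            raise DomainError(f"reference drug {reference_id!r} not in panel")
        self.reference = by_id[reference_id]
        self.candidates = [d for d in drugs if d.drug_id != reference_id]
        if not self.candidates:
            raise DomainError("screen needs at least one candidate drug")
        if self.config.corpus_scope == "target_union" and corpus is not None:
            union = set(self.reference.targets.targets)
            for c in self.candidates:
                union |= set(c.targets.targets)
            corpus = corpus.restricted_to(union)
        self.corpus = corpus

    @classmethod
    def from_files(cls, network_path: str | Path,
                   disease_genes_path: str | Path,
                   targets_path: str | Path,
                   smiles_path: str | Path | None = None,
                   sites_path: str | Path | None = None,
                   obo_path: str | Path | None = None,
                   annotations_path: str | Path | None = None,
                   reference_id: str = "LEF",
                   config: RunConfig | str | Path | None = None
                   ) -> "SynergyScreen":
        """Build a screen from the on-disk file formats."""
        if not isinstance(config, RunConfig):
            config = load_config(config)
        background = network.load_edge_list(network_path)
        genes = network.GeneSet.from_file(disease_genes_path,
                                          label="disease genes")
        targets = read_target_table(targets_path)
        smiles = chem.read_smiles_file(smiles_path) if smiles_path else {}
        sites = chem.read_sites_file(sites_path) if sites_path else {}
        corpus = None
        if obo_path and annotations_path:
            corpus = gofunction.GOAnnotationCorpus.from_files(
                obo_path, annotations_path)
        drugs = [DrugRecord(d, ts, smiles.get(d), sites.get(d))
                 for d, ts in targets.items()]
        return cls(background, genes, drugs, reference_id, corpus, config)

    def _scoring_network(self, cand: DrugRecord | None = None
                         ) -> network.InteractionNetwork:
        cfg = self.config
        if cfg.scoring_graph == "background":
            return self.background
        ids = set(self.disease_genes.ids)
        if cfg.scoring_graph == "disease_plus_targets":
            ids |= set(self.reference.targets.targets)
            if cand is not None:
                ids |= set(cand.targets.targets)
        genes = network.GeneSet(frozenset(ids), cfg.scoring_graph)
        return network.induce_subnetwork(self.background, genes)

    def fit(self) -> "ScreenResults":
        """Run the screen and return ranked results."""
        cfg = self.config
        if cfg.scoring_graph == "disease_plus_targets":
            # the scoring graph depends on the candidate pair
            rows = []
            scoring_net = None
            for cand in self.candidates:
                net = self._scoring_network(cand)
                cs = network.compute_centralities(net, damping=cfg.damping)
                part = assemble_scores(self.reference, [cand], net, cs,
                                       self.corpus, cfg)
                rows.append(part)
                scoring_net = net
            raw = pd.concat(rows, ignore_index=True)
            centralities = cs
        else:
            scoring_net = self._scoring_network()
            centralities = network.compute_centralities(
                scoring_net, damping=cfg.damping)
            raw = assemble_scores(self.reference, self.candidates,
                                  scoring_net, centralities, self.corpus,
                                  cfg)
        table = normalize_and_rank(raw, total_rule=cfg.total_rule)
        return ScreenResults(self, table, scoring_net, centralities)


class ScreenResults:
    """Ranked screen output with diagnostics.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per candidate with raw axes, normalized triple, diagonal
        total and rank (columns :data:`RANKED_COLUMNS`).
    scoring_network : InteractionNetwork
        The network centralities and distances were computed on.
    centralities : pandas.DataFrame
        Per-node betweenness, closeness, PageRank, CS.
    """

    def __init__(self, screen: SynergyScreen, table: pd.DataFrame,
                 scoring_network: network.InteractionNetwork,
                 centralities: pd.DataFrame):
        self.screen = screen
        self.table = table
        self.scoring_network = scoring_network
        self.centralities = centralities

    @property
    def top(self) -> str:
        """drug_id of the rank-1 candidate."""
        return str(self.table.iloc[0]["drug_id"])

    def rank_of(self, drug_id: str) -> int:
        row = self.table[self.table["drug_id"] == drug_id]
        if row.empty:
            raise DomainError(f"drug {drug_id!r} not in the screen")
        return int(row["rank"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        write_ranked_table(self.table, path)

    def summary(self) -> str:
        """Human-readable report of the screen."""
        scr = self.screen
        lines = [
            "Synergy screen results",
            "=" * 54,
            f"reference drug:     {scr.reference.drug_id}",
            f"candidates:         {len(scr.candidates)}",
            f"scoring network:    {self.scoring_network.n_nodes()} nodes, "
            f"{self.scoring_network.n_edges()} edges "
            f"({scr.config.scoring_graph})",
            f"total rule:         {scr.config.total_rule}",
            "",
            self.table.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def plot(self, path: str | Path | None = None):
        """3D scatter of the normalized axes with the unit diagonal.

        Requires matplotlib; returns the figure.
        """
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        t = self.table
        ax.scatter(t["norm_x"], t["norm_y"], t["norm_z"], c=t["total"],
                   cmap="viridis", depthshade=False)
        ax.plot([0, 1], [0, 1], [0, 1], "b-", lw=1, label="diagonal")
        top = t.iloc[0]
        ax.text(top["norm_x"], top["norm_y"], top["norm_z"],
                f' {top["drug_id"]}')
        ax.set_xlabel("target network")
        ax.set_ylabel("function")
        ax.set_zlabel("chemical similarity")
        ax.legend()
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
        return fig
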