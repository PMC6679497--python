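"""2D LINGO and 3D pharmacophore-overlap similarity of drug structures.

2D: a canonical SMILES string, with every ring-closure label rewritten to
'0', is decomposed into its overlapping length-q substrings (LINGOs,
q = 4 by default). Two profiles are compared with the count-based
Tanimoto-style mean

    S_2d = (1/m) * sum_k [ 1 - |N_i,k - N_j,k| / (N_i,k + N_j,k) ]

over the m unique LINGOs of the union (absent LINGOs count 0).

3D: each drug is a set of typed pharmacophore sites (acceptor, donor,
hydrophobe, negative, positive, aromatic ring) at 3D coordinates in a
shared, pre-aligned frame. The overlap of two site sets is a Gaussian
sum over same-type site pairs, O = sum exp(-d^2 / sigma^2), and the score
is the cross-overlap normalized by the larger self-overlap, clamped to
[0, 1]. The total structural score is S_similarity = S_2d + S_3d.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import (DomainError, InputFormatError, InputIOError,
                     UndefinedScoreError)

SITE_TYPES = frozenset("ADHNPR")  # acceptor, donor, hydrophobe, neg, pos, ring


@dataclass(frozen=True)
class SmilesString:
    """Raw SMILES plus the ring-digit-substituted form used for LINGOs."""

    drug_id: str
    raw: str
    processed: str


def preprocess_smiles(raw: str, drug_id: str = "") -> SmilesString:
    """Rewrite every ring-closure label of a SMILES string to '0'.

    Only digits outside square brackets are touched (single digits become
    '0', two-digit ``%nn`` labels become ``%00``); isotope, charge and
    H-count digits inside brackets are preserved. The input is expected
    to be canonical SMILES already — canonicalization is the caller's
    responsibility.
    """
    if not raw:
        raise DomainError("empty SMILES string")
    out: list[str] = []
    depth = 0
    i = 0
    while i < len(raw):
        c = raw[i]
        if c == "[":
            depth += 1
            out.append(c)
        elif c == "]":
            depth -= 1
            if depth < 0:
                raise InputFormatError(
                    f"unbalanced ']' in SMILES {raw!r}")
            out.append(c)
        elif depth == 0 and c == "%" and i + 3 <= len(raw) \
                and raw[i + 1:i + 3].isdigit():
            out.append("%00")
            i += 3
            continue
        elif depth == 0 and c.isdigit():
            out.append("0")
        else:
            out.append(c)
        i += 1
    if depth != 0:
        raise InputFormatError(f"unbalanced '[' in SMILES {raw!r}")
    return SmilesString(drug_id, raw, "".join(out))


@dataclass(frozen=True)
class LingoProfile:
    """Multiset of length-q substrings of a processed SMILES string."""

    drug_id: str
    q: int
    counts: tuple[tuple[str, int], ...]

    def as_counter(self) -> Counter:
        return Counter(dict(self.counts))


def lingo_profile(s: SmilesString, q: int = 4) -> LingoProfile:
    """Count all overlapping length-q substrings (stride 1).

    A string shorter than q yields itself as a single LINGO, so the
    window count is always max(len - q + 1, 1).
    """
    if q < 1:
        raise DomainError(f"LINGO length q must be >= 1, got {q}")
    text = s.processed
    if len(text) < q:
        counts = Counter([text])
    else:
        counts = Counter(text[i:i + q] for i in range(len(text) - q + 1))
    return LingoProfile(s.drug_id, q, tuple(sorted(counts.items())))


def lingosim(p1: LingoProfile, p2: LingoProfile) -> float:
    """LINGO profile similarity in [0, 1]; 1 iff the profiles coincide."""
    if p1.q != p2.q:
        raise DomainError(
            f"LINGO profiles built with different q: {p1.q} vs {p2.q}")
    c1, c2 = p1.as_counter(), p2.as_counter()
    union = set(c1) | set(c2)
    total = 0.0
    for k in union:
        a, b = c1.get(k, 0), c2.get(k, 0)
        total += 1.0 - abs(a - b) / (a + b)
    return total / len(union)


@dataclass(frozen=True)
class PharmacophoreSiteSet:
    """Typed 3D feature points of one drug, pre-aligned to a shared frame."""

    drug_id: str
    sites: tuple[tuple[str, float, float, float], ...]

    def __post_init__(self):
        for st, x, y, z in self.sites:
            if st not in SITE_TYPES:
                raise InputFormatError(
                    f"site type {st!r} not in {sorted(SITE_TYPES)}")
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise InputFormatError(
                    f"non-finite coordinate in site set {self.drug_id!r}")

    def __len__(self) -> int:
        return len(self.sites)


def site_overlap(a: PharmacophoreSiteSet, b: PharmacophoreSiteSet,
                 sigma: float = 1.0) -> float:
    """Gaussian overlap of two site sets: sum over same-type pairs.

    O(a, b) = sum over pairs (s in a, t in b) with matching type of
    exp(-d(s,t)^2 / sigma^2). The self-overlap O(a, a) is computed the
    same way and therefore includes intra-set same-type cross terms.
    """
    if len(a) == 0 or len(b) == 0:
        raise UndefinedScoreError(
            f"pharmacophore overlap of empty site set "
            f"({a.drug_id!r}: {len(a)}, {b.drug_id!r}: {len(b)})",
            code="score.empty_sites")
    if sigma <= 0:
        raise DomainError(f"sigma must be > 0, got {sigma}")
    total = 0.0
    for st_a, xa, ya, za in a.sites:
        for st_b, xb, yb, zb in b.sites:
            if st_a != st_b:
                continue
            d2 = (xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2
            total += math.exp(-d2 / (sigma * sigma))
    return total


def s_3d(a: PharmacophoreSiteSet, b: PharmacophoreSiteSet,
         sigma: float = 1.0) -> float:
    """3D pharmacophore similarity: cross-overlap over the larger
    self-overlap, clamped to [0, 1]."""
    cross = site_overlap(a, b, sigma)
    self_max = max(site_overlap(a, a, sigma), site_overlap(b, b, sigma))
    if self_max == 0.0:
        return 0.0
    return min(1.0, max(0.0, cross / self_max))


def s_similarity(s2d: float, s3d: float) -> float:
    """Total structural similarity: S_2d + S_3d, in [0, 2]."""
    return s2d + s3d


def read_smiles_file(path: str | Path) -> dict[str, SmilesString]:
    """Read a .smi file: one 'SMILES<whitespace>drug_id' record per line."""
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputIOError(f"cannot read SMILES file {path}: {exc}") from exc
    records: dict[str, SmilesString] = {}
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        cols = stripped.split()
        if len(cols) < 2:
            raise InputFormatError(
                f"{path}:{lineno}: expected 'SMILES<ws>drug_id'")
        smiles, drug_id = cols[0], cols[1]
        records[drug_id] = preprocess_smiles(smiles, drug_id)
    return records


def read_sites_file(path: str | Path) -> dict[str, PharmacophoreSiteSet]:
    """Read a pharmacophore site TSV with header
    drug_id, site_type, x, y, z."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"drug_id": str, "site_type": str})
    except OSError as exc:
        raise InputIOError(f"cannot read site table {path}: {exc}") from exc
    required = ["drug_id", "site_type", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"{path}: missing required column(s) {missing}")
    out: dict[str, PharmacophoreSiteSet] = {}
    for drug_id, grp in df.groupby("drug_id", sort=False):
        sites = tuple((row.site_type, float(row.x), float(row.y),
                       float(row.z)) for row in grp.itertuples(index=False))
        out[str(drug_id)] = PharmacophoreSiteSet(str(drug_id), sites)
    return out
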