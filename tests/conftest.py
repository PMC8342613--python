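"""Shared builders and independent brute-force oracles for the suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from acaritax.distances import DistanceMatrix
from acaritax.io import ReferenceLibrary, SequenceRecord


def make_record(
    rid: str,
    seq: str,
    bin_id: str = "BIN:A",
    order: str = "order01",
    family: str = "order01_fam01",
) -> SequenceRecord:
    return SequenceRecord(rid, bin_id, order, family, seq)


def make_library(records) -> ReferenceLibrary:
    return ReferenceLibrary(list(records))


def make_dm(ids, dist: dict[tuple[str, str], float], overlap_bp: int = 100) -> DistanceMatrix:
    """DistanceMatrix from a sparse {(id_a, id_b): d} mapping."""
    n = len(ids)
    d = np.full((n, n), 0.9)  # unspecified pairs sit far apart
    np.fill_diagonal(d, 0.0)
    for (a, b), v in dist.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    ov = np.full((n, n), overlap_bp, dtype=np.int64)
    return DistanceMatrix(list(ids), d, ov)


def random_aligned_seqs(rng: np.random.Generator, n: int, width: int,
                        alphabet: str = "ACGT-N") -> list[str]:
    chars = np.array(list(alphabet))
    return ["".join(rng.choice(chars, width)) for _ in range(n)]


def make_results(correct_sims, incorrect_sims, rank: str = "family") -> pd.DataFrame:
    """Identification-results frame with prescribed similarity/correctness."""
    rows = []
    for k, s in enumerate(correct_sims):
        rows.append((f"q{k:03d}", f"h{k:03d}", float(s), 600, True))
    off = len(rows)
    for k, s in enumerate(incorrect_sims):
        rows.append((f"q{off + k:03d}", f"h{off + k:03d}", float(s), 600, False))
    df = pd.DataFrame(
        rows, columns=["query_id", "hit_id", "similarity", "overlap_bp", "flag"]
    )
    df["true_order"] = "order01"
    df["true_family"] = "order01_fam01"
    df["predicted_order"] = "order01"
    df["predicted_family"] = "order01_fam01"
    df["correct_order"] = df["flag"]
    df["correct_family"] = df["flag"]
    return df.drop(columns="flag")


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)

def oracle_p_distance(a: str, b: str) -> tuple[float, int]:
    """Character-by-character p-distance with pairwise deletion."""
    mism = comp = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            comp += 1
            if x != y:
                mism += 1
    return (mism / comp if comp else math.nan), comp


def oracle_clusters(ids, d: np.ndarray, threshold: float) -> list[frozenset]:
    """Transitive closure over all edges d < threshold via union-find."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(len(ids)), 2):
        if not math.isnan(d[i, j]) and d[i, j] < threshold:
            parent[find(ids[i])] = find(ids[j])
    groups: dict[str, set] = {}
    for rid in ids:
        groups.setdefault(find(rid), set()).add(rid)
    return [frozenset(g) for g in groups.values()]


def oracle_silhouette(ids, d: np.ndarray, labels: dict[str, int]) -> dict[str, float]:
    """Per-definition silhouette, quadratic time."""
    out = {}
    clusters: dict[int, list[int]] = {}
    for k, rid in enumerate(ids):
        clusters.setdefault(labels[rid], []).append(k)
    for k, rid in enumerate(ids):
        own = clusters[labels[rid]]
        if len(own) == 1:
            out[rid] = 0.0
            continue
        a = sum(d[k, m] for m in own if m != k) / (len(own) - 1)
        b = min(
            sum(d[k, m] for m in members) / len(members)
            for lab, members in clusters.items()
            if lab != labels[rid]
        )
        out[rid] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return out


def oracle_auc(correct_sims, incorrect_sims) -> float:
    """Concordance-pair AUC, ties counted 1/2."""
    num = 0.0
    for c in correct_sims:
        for w in incorrect_sims:
            if c > w:
                num += 1.0
            elif c == w:
                num += 0.5
    return num / (len(correct_sims) * len(incorrect_sims))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
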