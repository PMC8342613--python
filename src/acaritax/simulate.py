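"""Seeded synthetic barcode libraries with a known order→family→BIN
hierarchy and controlled divergence structure.

Sequences are evolved down a star-within-star hierarchy: a single root,
one ancestor per order, family ancestors within each order, BIN
ancestors within each family and member sequences within each BIN.
Substitutions are applied as independent per-site replacement with a
uniformly drawn base (Jukes–Cantor-like), so repeated hits at the same
site make realized p-distances saturate below 0.75 at high loads — the
same saturation that flattens deep-divergence estimates in real COI
data.  Branch replacement probabilities are chosen so that the expected
p-distance between two sister taxa matches the configured target: for a
pairwise target t, each branch replaces sites with probability
``q = 1 - sqrt(1 - t / 0.75)``.

Divergence targets are expectations, not guarantees; realized values
carry binomial noise of order ``sqrt(p (1-p) / width)`` per pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .io import ReferenceLibrary, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SyntheticConfigError(ValueError):
    """Unsatisfiable generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Counts default to the study grid used throughout the package: 4
    orders x 10 families, BIN counts drawn uniformly from 1–14 per family
    (≈300 BINs, with occasional single-BIN families) and 4 sequences per
    BIN (≈1200 records).  Divergence targets mirror the structure of a
    continental mite barcode library: intra-BIN below ~2%, between-BIN
    (within family) 4–25%, an interfamily floor of 10% and an interorder
    floor of 18%.  A fraction ``bin_sibling_prob`` of BINs bud off an
    existing BIN at shallow (2–5.5%) divergence, giving the allied-BIN
    structure that 5% dilution collapses (roughly a quarter of BINs merge
    at the 5% cut, as in a real library).
    """

    n_orders: int = 4
    families_per_order: int | tuple[int, int] = 10
    bins_per_family: int | tuple[int, int] = (1, 14)
    seqs_per_bin: int = 4
    alignment_width: int = 658
    intra_bin_max: float = 0.02
    interbin_range: tuple[float, float] = (0.04, 0.25)
    bin_sibling_prob: float = 0.45
    sibling_range: tuple[float, float] = (0.02, 0.055)
    interfamily_floor: float = 0.10
    interorder_floor: float = 0.18
    ambiguity_rate: float = 0.002
    truncation_fraction: float = 0.0
    truncation_region: tuple[int, int] = (196, 658)
    n_decoys: int = 0
    decoy_divergence: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.intra_bin_max < self.interfamily_floor <= self.interorder_floor:
            raise SyntheticConfigError(
                "divergence floors must satisfy "
                "intra_bin_max < interfamily_floor <= interorder_floor"
            )
        for name in ("intra_bin_max", "interfamily_floor", "interorder_floor",
                     "ambiguity_rate", "truncation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticConfigError(f"{name}={v} outside [0, 1]")
        for rng_name in ("interbin_range", "sibling_range"):
            lo, hi = getattr(self, rng_name)
            if not 0.0 < lo <= hi < 0.74:
                raise SyntheticConfigError(
                    f"{rng_name} must satisfy 0 < lo <= hi < 0.74"
                )
        if not 0.0 <= self.bin_sibling_prob <= 1.0:
            raise SyntheticConfigError("bin_sibling_prob outside [0, 1]")
        if self.interorder_floor >= 0.70:
            raise SyntheticConfigError(
                "interorder_floor too close to the 0.75 saturation ceiling"
            )
        if self.n_decoys > 0 and self.decoy_divergence <= self.interorder_floor:
            raise SyntheticConfigError("decoy_divergence must exceed interorder_floor")
        if self.interfamily_floor * self.alignment_width < 5:
            raise SyntheticConfigError(
                "alignment too short to resolve the interfamily floor "
                f"({self.interfamily_floor} over {self.alignment_width} columns)"
            )


@dataclass
class TruthTable:
    """Per-record generating lineage and branch substitution counts."""

    frame: pd.DataFrame  # id, order, family, bin_id, subs_* per branch

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _branch_q(pair_target: float) -> float:
    """Per-branch replacement probability so that two sister branches of
    this weight realize an expected pairwise p-distance ``pair_target``."""
    if not 0.0 <= pair_target < 0.745:
        raise SyntheticConfigError(
            f"pairwise divergence target {pair_target} unreachable "
            "(saturation ceiling is 0.75)"
        )
    return 1.0 - math.sqrt(1.0 - pair_target / 0.75)


def _single_branch_q(pair_target: float) -> float:
    """Replacement probability for a single connecting branch realizing an
    expected pairwise p-distance ``pair_target`` on its own."""
    if not 0.0 <= pair_target < 0.745:
        raise SyntheticConfigError(
            f"pairwise divergence target {pair_target} unreachable"
        )
    return pair_target / 0.75


def _evolve(parent: np.ndarray, q: float, rng: np.random.Generator):
    """Replace each site with prob q by a uniform base; returns the child
    and the count of sites that actually changed."""
    mask = rng.random(parent.size) < q
    child = parent.copy()
    child[mask] = rng.integers(0, 4, int(mask.sum()))
    return child, int((child != parent).sum())


def _count(spec: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(spec, tuple):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def _to_string(codes: np.ndarray, ambig_mask: np.ndarray) -> str:
    out = _BASES[codes].copy()
    out[ambig_mask] = ord("N")
    return out.tobytes().decode("ascii")


def generate_library(config: SyntheticConfig) -> tuple[ReferenceLibrary, TruthTable]:
    """Evolve a full library down the configured hierarchy.

    Fully reproducible from ``config.seed``; the same config yields
    byte-identical sequences and labels.
    """
    rng = np.random.default_rng(config.seed)
    width = config.alignment_width
    root = rng.integers(0, 4, width).astype(np.uint8)

    q_order = _branch_q(config.interorder_floor)
    q_family = _branch_q(config.interfamily_floor)
    q_member = _branch_q(config.intra_bin_max * 0.5)

    records: list[SequenceRecord] = []
    truth_rows = []
    seq_no = 0
    bin_no = 0
    for o in range(config.n_orders):
        order_name = f"order{o + 1:02d}"
        order_anc, subs_o = _evolve(root, q_order, rng)
        n_fam = _count(config.families_per_order, rng)
        for f in range(n_fam):
            family_name = f"{order_name}_fam{f + 1:02d}"
            fam_anc, subs_f = _evolve(order_anc, q_family, rng)
            n_bins = _count(config.bins_per_family, rng)
            bin_ancestors: list[np.ndarray] = []
            for _b in range(n_bins):
                bin_no += 1
                bin_name = f"BIN:{bin_no:05d}"
                # congeneric structure: a new BIN sometimes buds off an
                # existing BIN at shallow divergence rather than branching
                # straight from the family ancestor, so that 5% dilution
                # has allied BINs to merge
                if bin_ancestors and rng.random() < config.bin_sibling_prob:
                    parent = bin_ancestors[int(rng.integers(len(bin_ancestors)))]
                    # one connecting branch, so the full pairwise target
                    # divergence goes on this single branch
                    q_bin = _single_branch_q(rng.uniform(*config.sibling_range))
                else:
                    parent = fam_anc
                    q_bin = _branch_q(rng.uniform(*config.interbin_range))
                bin_anc, subs_b = _evolve(parent, q_bin, rng)
                bin_ancestors.append(bin_anc)
                for _s in range(config.seqs_per_bin):
                    seq_no += 1
                    rid = f"SEQ{seq_no:05d}"
                    codes, subs_m = _evolve(bin_anc, q_member, rng)
                    ambig = rng.random(width) < config.ambiguity_rate
                    records.append(
                        SequenceRecord(
                            rid, bin_name, order_name, family_name,
                            _to_string(codes, ambig),
                        )
                    )
                    truth_rows.append(
                        (rid, order_name, family_name, bin_name,
                         subs_o, subs_f, subs_b, subs_m)
                    )

    lib = ReferenceLibrary(records, alignment_width=width)
    if config.truncation_fraction > 0:
        lib = truncate_records(
            lib, config.truncation_fraction, config.truncation_region,
            seed=config.seed,
        )
    truth = TruthTable(
        pd.DataFrame(
            truth_rows,
            columns=[
                "id", "order", "family", "bin_id",
                "subs_order_branch", "subs_family_branch",
                "subs_bin_branch", "subs_member_branch",
            ],
        )
    )
    return lib, truth


def inject_decoys(lib: ReferenceLibrary, config: SyntheticConfig) -> ReferenceLibrary:
    """Append non-target outgroup records (one per decoy lineage) whose
    divergence from every target record exceeds the interorder floor.
    Emulates far-taxon reference records that attract misassignments at
    low similarity.  With ``n_decoys == 0`` this is the identity."""
    if config.n_decoys == 0:
        return lib
    rng = np.random.default_rng([config.seed, 0xDEC0])
    width = config.alignment_width
    if lib.alignment_width != width:
        raise ValueError("library width does not match decoy config")
    root = np.random.default_rng(config.seed).integers(0, 4, width).astype(np.uint8)
    q_decoy = _branch_q(config.decoy_divergence)
    existing = set(lib.ids)
    records = list(lib.records)
    for i in range(config.n_decoys):
        rid = f"DEC{i + 1:05d}"
        if rid in existing:
            raise ValueError(f"decoy id {rid} collides with library")
        codes, _ = _evolve(root, q_decoy, rng)
        records.append(
            SequenceRecord(
                rid,
                f"BIN:DEC{i + 1:03d}",
                f"decoy_order{i + 1:02d}",
                f"decoy_fam{i + 1:02d}",
                _to_string(codes, np.zeros(width, bool)),
            )
        )
    return ReferenceLibrary(records, alignment_width=width, region=lib.region)


def truncate_records(
    lib: ReferenceLibrary,
    fraction: float,
    region: tuple[int, int],
    seed: int = 0,
) -> ReferenceLibrary:
    """Gap-mask a seeded random subset of records outside ``region``
    (1-based inclusive columns), emulating shorter metabarcoding reads."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0.0:
        return lib
    start, end = region
    if not 1 <= start <= end <= lib.alignment_width:
        raise ValueError(f"region {region} out of range")
    rng = np.random.default_rng([seed, 0x7A])
    n_pick = int(round(fraction * len(lib)))
    picked = set(rng.choice(len(lib), size=n_pick, replace=False).tolist())
    records = []
    for i, r in enumerate(lib.records):
        if i in picked:
            seq = "-" * (start - 1) + r.seq[start - 1 : end] + "-" * (
                lib.alignment_width - end
            )
            records.append(_dc_replace(r, seq=seq))
        else:
            records.append(r)
    return ReferenceLibrary(records, alignment_width=lib.alignment_width, region=lib.region)
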