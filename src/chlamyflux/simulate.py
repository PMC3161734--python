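"""Synthetic inputs with known ground truth.

Three generator families mirror the three kinds of real input the pipeline
consumes: small stoichiometric networks with analytically known EFM sets,
3'-UTR nucleotide sequences with planted (UG)k repeats at controlled rates,
and protein FASTA files drawn from a specified residue-frequency vector.
All generators are deterministic under a single integer seed; each family
draws from its own named substream so fixtures do not depend on call order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from .network import Metabolite, MetabolicNetwork, ModelConfig, Reaction

__all__ = [
    "SyntheticSpec",
    "toy_network",
    "TOY_NETWORKS",
    "random_network",
    "planted_utrs",
    "synthetic_proteome",
    "AA_ALPHABET",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent of the order generators are called in."""
    digest = hashlib.sha256(stream.encode()).digest()
    salt = int.from_bytes(digest[:4], "little")
    return np.random.default_rng([seed, salt])


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for the synthetic generators (all families in one record)."""

    seed: int = 0
    # network family
    n_pathways: int = 2
    pathway_length: int = 4
    n_shared_metabolites: int = 1
    reversibility_fraction: float = 0.0
    carbon_count: int = 3
    # UTR family
    n_sequences: int = 10
    utr_length: int = 200
    motif_rate: float = 1.0
    repeat_counts: tuple[int, ...] = (7,)
    min_repeats: int = 7
    # proteome family
    n_proteins: int = 50
    mean_protein_length: int = 300
    residue_frequencies: tuple[float, ...] = tuple([1.0 / 20] * 20)

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_rate <= 1.0:
            raise ValueError("motif_rate must lie in [0, 1]")
        if not 0.0 <= self.reversibility_fraction <= 1.0:
            raise ValueError("reversibility_fraction must lie in [0, 1]")
        if abs(sum(self.residue_frequencies) - 1.0) > 1e-9:
            raise ValueError("residue_frequencies must sum to 1")
        if len(self.residue_frequencies) != 20:
            raise ValueError("residue_frequencies must have 20 entries")


# ---------------------------------------------------------------------------
# Toy networks with analytically known EFM sets
# ---------------------------------------------------------------------------


def _net(name, mets, rxns, external, carbon_sources=(), targets=()):
    metabolites = [Metabolite(m, carbon_count=c, is_external=m in external) for m, c in mets]
    reactions = [
        Reaction(rid, {m: Fraction(c) for m, c in stoich.items()}, reversible=rev)
        for rid, stoich, rev in rxns
    ]
    cfg = ModelConfig(
        external=frozenset(external),
        carbon_sources=frozenset(carbon_sources),
        targets=tuple(targets),
    )
    return MetabolicNetwork(metabolites, reactions, name=name).with_config(cfg)


def _toy_t1():
    """Linear chain A_ext -> A -> B -> B_ext: exactly one EFM, all fluxes 1."""
    net = _net(
        "T1_linear",
        [("A_ext", 1), ("A", 1), ("B", 1), ("B_ext", 1)],
        [
            ("R1", {"A_ext": -1, "A": 1}, False),
            ("R2", {"A": -1, "B": 1}, False),
            ("R3", {"B": -1, "B_ext": 1}, False),
        ],
        external={"A_ext", "B_ext"},
        carbon_sources={"A_ext"},
        targets=("B_ext",),
    )
    expected = [{"R1": 1, "R2": 1, "R3": 1}]
    return net, expected


def _toy_t2():
    """Diamond: two parallel branches S -> A -> {B|C} -> P, two EFMs."""
    net = _net(
        "T2_diamond",
        [("S_ext", 2), ("A", 2), ("B", 2), ("C", 2), ("P", 2), ("P_ext", 2)],
        [
            ("R1", {"S_ext": -1, "A": 1}, False),
            ("R2", {"A": -1, "B": 1}, False),
            ("R3", {"A": -1, "C": 1}, False),
            ("R4", {"B": -1, "P": 1}, False),
            ("R5", {"C": -1, "P": 1}, False),
            ("R6", {"P": -1, "P_ext": 1}, False),
        ],
        external={"S_ext", "P_ext"},
        carbon_sources={"S_ext"},
        targets=("P_ext",),
    )
    expected = [
        {"R1": 1, "R2": 1, "R4": 1, "R6": 1},
        {"R1": 1, "R3": 1, "R5": 1, "R6": 1},
    ]
    return net, expected


def _toy_t3():
    """Diamond with a reversible cross-edge B <-> C: four EFMs, no two-cycle.

    The two plain branch routes survive, and the cross-edge adds one route
    per direction (B->C joining the C branch, C->B joining the B branch).
    The count is pinned against the brute-force reference enumerator in the
    test suite.
    """
    net = _net(
        "T3_revcross",
        [("S_ext", 2), ("A", 2), ("B", 2), ("C", 2), ("P", 2), ("P_ext", 2)],
        [
            ("R1", {"S_ext": -1, "A": 1}, False),
            ("R2", {"A": -1, "B": 1}, False),
            ("R3", {"A": -1, "C": 1}, False),
            ("R4", {"B": -1, "P": 1}, False),
            ("R5", {"C": -1, "P": 1}, False),
            ("R6", {"P": -1, "P_ext": 1}, False),
            ("R7", {"B": -1, "C": 1}, True),
        ],
        external={"S_ext", "P_ext"},
        carbon_sources={"S_ext"},
        targets=("P_ext",),
    )
    expected = [
        {"R1": 1, "R2": 1, "R4": 1, "R6": 1},
        {"R1": 1, "R3": 1, "R5": 1, "R6": 1},
        {"R1": 1, "R2": 1, "R7": 1, "R5": 1, "R6": 1},
        {"R1": 1, "R3": 1, "R7": -1, "R4": 1, "R6": 1},
    ]
    return net, expected


def _toy_t4():
    """Decarboxylating chain: one EFM with carbon yield exactly 2/3.

    X (3 C) is converted to P (2 C) with release of one CO2, so the single
    mode's yield for target P_ext on source X_ext is (1*2)/(1*3) = 2/3.
    """
    net = _net(
        "T4_co2",
        [("X_ext", 3), ("X", 3), ("P", 2), ("CO2", 1), ("P_ext", 2), ("CO2_ext", 1)],
        [
            ("R1", {"X_ext": -1, "X": 1}, False),
            ("R2", {"X": -1, "P": 1, "CO2": 1}, False),
            ("R3", {"P": -1, "P_ext": 1}, False),
            ("R4", {"CO2": -1, "CO2_ext": 1}, False),
        ],
        external={"X_ext", "P_ext", "CO2_ext"},
        carbon_sources={"X_ext"},
        targets=("P_ext",),
    )
    expected = [{"R1": 1, "R2": 1, "R3": 1, "R4": 1}]
    return net, expected


TOY_NETWORKS = {
    "T1_linear": _toy_t1,
    "T2_diamond": _toy_t2,
    "T3_revcross": _toy_t3,
    "T4_co2": _toy_t4,
}


def toy_network(name: str) -> tuple[MetabolicNetwork, list[dict[str, int]]]:
    """Return a named toy fixture and its analytically known EFM flux dicts.

    T3 ships with the two modes whose existence is obvious by inspection;
    its full EFM set (three modes once the shunt's forward route is
    counted) is pinned down by the brute-force reference enumerator in the
    test suite.
    """
    try:
        return TOY_NETWORKS[name]()
    except KeyError:
        raise ValueError(
            f"unknown toy network {name!r}; choose from {sorted(TOY_NETWORKS)}"
        ) from None


# ---------------------------------------------------------------------------
# Random carbon-balanced networks
# ---------------------------------------------------------------------------


def random_network(spec: SyntheticSpec) -> MetabolicNetwork:
    """Random carbon-balanced network built from source->sink linear pathways
    that share intermediate metabolites.

    Every metabolite carries the same carbon count and every reaction is
    1-to-1, so carbon balance holds by construction; shared intermediates
    create branch points and therefore nontrivial EFM structure.  At least
    one route from the designated carbon source to the designated target is
    guaranteed.  Deterministic under ``spec.seed``.
    """
    if spec.n_pathways < 1:
        raise ValueError("need at least one pathway")
    if spec.pathway_length < 2:
        raise ValueError("pathway_length must be >= 2")
    rng = _rng(spec.seed, "network")
    c = spec.carbon_count
    mets: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []

    def ensure(mid: str, external: bool = False) -> str:
        if mid not in mets:
            mets[mid] = Metabolite(mid, carbon_count=c, is_external=external)
        return mid

    ensure("SRC_ext", external=True)
    ensure("SINK_ext", external=True)
    shared = [ensure(f"X{i}") for i in range(spec.n_shared_metabolites)]
    rid = 0
    for p in range(spec.n_pathways):
        # interior nodes: mix of pathway-private and shared metabolites
        interior: list[str] = []
        for step in range(spec.pathway_length - 1):
            if shared and rng.random() < 0.5:
                interior.append(str(rng.choice(shared)))
            else:
                interior.append(ensure(f"P{p}_{step}"))
        chain = ["SRC_ext"] + interior + ["SINK_ext"]
        for a, b in zip(chain, chain[1:]):
            if a == b:
                continue
            rev = bool(rng.random() < spec.reversibility_fraction)
            reactions.append(
                Reaction(f"R{rid}", {a: Fraction(-1), b: Fraction(1)}, reversible=rev)
            )
            rid += 1
    cfg = ModelConfig(
        external=frozenset({"SRC_ext", "SINK_ext"}),
        carbon_sources=frozenset({"SRC_ext"}),
        targets=("SINK_ext",),
    )
    net = MetabolicNetwork(
        list(mets.values()), reactions, name=f"random_seed{spec.seed}"
    )
    return net.with_config(cfg)


# ---------------------------------------------------------------------------
# Planted-motif UTR sets
# ---------------------------------------------------------------------------

_NON_UG = "ACA"  # flank that can extend no UG run


def _background(rng: np.random.Generator, length: int, max_run: int) -> str:
    """Random RNA with every UG run capped strictly below ``max_run`` units."""
    bases = "ACGU"
    out: list[str] = []
    run = 0  # current number of trailing complete UG units
    while len(out) < length:
        b = bases[rng.integers(0, 4)]
        out.append(b)
        s = "".join(out[-2 * max_run :])
        # count trailing complete UG units
        run = 0
        while s.endswith("UG" * (run + 1)):
            run += 1
        if run >= max_run:
            out[-1] = "A"  # break the run
    return "".join(out[:length])


def planted_utrs(
    spec: SyntheticSpec,
) -> tuple[list[tuple[str, str]], list[tuple[str, int, int, int]]]:
    """Synthetic 3'-UTR set with planted maximal (UG)k repeats.

    Returns ``(records, truth)`` where records are ``(sequence_id, sequence)``
    and truth rows are ``(sequence_id, start, end, repeat_count)`` in 0-based
    half-open coordinates, listing only the planted runs (of any length —
    including deliberately sub-threshold ones).  Background sequence never
    contains a UG run of ``min_repeats`` units or more, and planted runs are
    flanked by non-extending bases, so they are maximal by construction.
    """
    rng = _rng(spec.seed, "utr")
    records: list[tuple[str, str]] = []
    truth: list[tuple[str, int, int, int]] = []
    for i in range(spec.n_sequences):
        sid = f"utr{i:04d}"
        seq = _background(rng, spec.utr_length, spec.min_repeats)
        if rng.random() < spec.motif_rate:
            k = int(rng.choice(spec.repeat_counts))
            motif = _NON_UG + "UG" * k + _NON_UG
            if len(motif) > len(seq):
                raise ValueError(
                    f"motif of {k} units does not fit in length {spec.utr_length}"
                )
            pos = int(rng.integers(0, len(seq) - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif) :]
            start = pos + len(_NON_UG)
            truth.append((sid, start, start + 2 * k, k))
        records.append((sid, seq))
    return records, truth


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Synthetic proteomes
# ---------------------------------------------------------------------------


def synthetic_proteome(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """Protein records sampled residue-wise from ``spec.residue_frequencies``.

    Sequence lengths are Poisson-distributed around ``mean_protein_length``
    (minimum 1).  Deterministic under ``spec.seed``.
    """
    rng = _rng(spec.seed, "proteome")
    freqs = np.asarray(spec.residue_frequencies, dtype=float)
    records = []
    for i in range(spec.n_proteins):
        length = max(1, int(rng.poisson(spec.mean_protein_length)))
        idx = rng.choice(20, size=length, p=freqs)
        seq = "".join(AA_ALPHABET[j] for j in idx)
        records.append((f"prot{i:04d}", seq))
    return records
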