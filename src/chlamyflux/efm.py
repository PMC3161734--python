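"""Elementary flux mode enumeration by the double description method.

An elementary flux mode (EFM) is a steady-state flux vector ``v`` with
``S v = 0`` over the internal metabolites, non-negative flux through every
irreversible reaction, and support (the set of active reactions) that is
minimal: no other admissible steady-state vector uses a proper subset of its
reactions.  The EFMs are the extreme rays of the flux cone after each
reversible reaction is split into a forward/backward pair.

The enumeration here is the classical iterative double description scheme:
start from the unit rays of the non-negative orthant, then impose the
steady-state constraint one internal metabolite at a time, keeping rays that
satisfy the new equality and the admissible pairwise combinations of
positive/negative rays.  A combination is kept only if the pair is adjacent,
decided by the combinatorial test: no third ray's support may be contained
in the union of the pair's supports.  All arithmetic is exact (arbitrary
precision integers after per-row scaling); floating point appears only in
reports.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .network import MetabolicNetwork

__all__ = [
    "FluxMode",
    "EfmSet",
    "EnumerationCapExceeded",
    "enumerate_efms",
    "overall_equation",
    "classify_by_target",
    "knockout_filter",
    "is_affected",
]

DEFAULT_MODE_CAP = 5_000_000


class EnumerationCapExceeded(RuntimeError):
    """Raised when the intermediate ray count exceeds the configured cap."""

    def __init__(self, n_rays: int, cap: int, rows_done: int, rows_total: int):
        super().__init__(
            f"enumeration aborted: {n_rays} rays after {rows_done}/{rows_total} "
            f"constraints exceeds cap {cap}"
        )
        self.n_rays = n_rays
        self.cap = cap
        self.rows_done = rows_done
        self.rows_total = rows_total


@dataclass(frozen=True)
class FluxMode:
    """One EFM: integer fluxes on the original (un-split) reactions.

    Fluxes on reversible reactions may be negative (the mode runs them
    backwards); the vector is scaled to the smallest integer vector with
    gcd 1.  ``overall`` is the mode's net external-metabolite equation.
    """

    fluxes: tuple[int, ...]
    reaction_ids: tuple[str, ...]
    overall: tuple[tuple[str, Fraction], ...]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(
            rid for rid, v in zip(self.reaction_ids, self.fluxes) if v != 0
        )

    def flux_dict(self) -> dict[str, int]:
        return {rid: v for rid, v in zip(self.reaction_ids, self.fluxes) if v != 0}

    def overall_dict(self) -> dict[str, Fraction]:
        return dict(self.overall)


@dataclass
class EfmSet:
    """The EFMs of one network, in deterministic (support-bitmask) order."""

    network: MetabolicNetwork
    reaction_ids: tuple[str, ...]
    vectors: list[tuple[int, ...]]
    elapsed_seconds: float = 0.0
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.vectors)

    def __iter__(self) -> Iterator[FluxMode]:
        for i in range(len(self.vectors)):
            yield self.mode(i)

    def mode(self, i: int) -> FluxMode:
        v = self.vectors[i]
        ov = overall_equation(v, self.network, self.reaction_ids)
        return FluxMode(v, self.reaction_ids, tuple(sorted(ov.items())))

    def supports(self) -> list[frozenset[str]]:
        return [
            frozenset(r for r, x in zip(self.reaction_ids, v) if x != 0)
            for v in self.vectors
        ]

    def overall_matrix(self) -> tuple[list[str], np.ndarray]:
        """(external ids, n_modes x n_external) net external stoichiometry.

        Entries are exact if the network stoichiometry is integer; returned
        as float64 for vectorised filtering.
        """
        ext_ids = [m.id for m in self.network.external_metabolites]
        eidx = {m: i for i, m in enumerate(ext_ids)}
        ridx = {r.id: r for r in self.network.reactions}
        E = np.zeros((len(ext_ids), len(self.reaction_ids)))
        for j, rid in enumerate(self.reaction_ids):
            for mid, c in ridx[rid].stoichiometry.items():
                if mid in eidx:
                    E[eidx[mid], j] = float(c)
        V = np.array(self.vectors, dtype=np.int64)
        return ext_ids, V @ E.T

    def subset(self, keep: Sequence[int]) -> "EfmSet":
        return EfmSet(
            self.network,
            self.reaction_ids,
            [self.vectors[i] for i in keep],
            self.elapsed_seconds,
            dict(self.stats),
        )

    # -- serialisation ---------------------------------------------------
    def network_hash(self) -> str:
        h = hashlib.sha256()
        for r in self.network.reactions:
            h.update(r.id.encode())
            h.update(r.equation().encode())
        h.update(",".join(sorted(m.id for m in self.network.external_metabolites)).encode())
        return h.hexdigest()[:16]

    def to_tsv(self, path: str | Path) -> None:
        """Wide TSV: one row per mode, one column per reaction."""
        with open(path, "w") as fh:
            fh.write(f"# network_hash={self.network_hash()} n_modes={len(self)}\n")
            fh.write("mode\t" + "\t".join(self.reaction_ids) + "\n")
            for i, v in enumerate(self.vectors):
                fh.write(f"M{i}\t" + "\t".join(str(x) for x in v) + "\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "network_hash": self.network_hash(),
            "reaction_ids": list(self.reaction_ids),
            "modes": [
                {
                    "support": [r for r, x in zip(self.reaction_ids, v) if x != 0],
                    "vector": [x for x in v if x != 0],
                }
                for v in self.vectors
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path, network: MetabolicNetwork) -> "EfmSet":
        payload = json.loads(Path(path).read_text())
        rids = tuple(payload["reaction_ids"])
        idx = {r: j for j, r in enumerate(rids)}
        vectors = []
        for m in payload["modes"]:
            v = [0] * len(rids)
            for r, x in zip(m["support"], m["vector"]):
                v[idx[r]] = x
            vectors.append(tuple(v))
        return cls(network, rids, vectors)


# ---------------------------------------------------------------------------
# Split-matrix construction (shared with the brute-force reference enumerator)
# ---------------------------------------------------------------------------


def split_internal_matrix(
    net: MetabolicNetwork,
) -> tuple[list[list[int]], list[tuple[int, int]]]:
    """Integer internal stoichiometric matrix with reversible reactions split.

    Returns ``(rows, columns)`` where each row is a dense integer list over
    the split columns and each column is ``(reaction_index, direction)``
    with direction +1 (forward) or -1 (backward copy of a reversible
    reaction).  Each row of the rational S is scaled by the LCM of its
    coefficient denominators, which leaves the kernel unchanged.
    """
    internal = net.internal_metabolites
    if not internal:
        raise ValueError("network has no internal metabolites")
    columns: list[tuple[int, int]] = [(j, +1) for j in range(len(net.reactions))]
    columns += [(j, -1) for j, r in enumerate(net.reactions) if r.reversible]
    met_index = {m.id: i for i, m in enumerate(internal)}
    frac_rows = [[Fraction(0)] * len(columns) for _ in internal]
    for k, (j, sgn) in enumerate(columns):
        for mid, c in net.reactions[j].stoichiometry.items():
            if mid in met_index:
                frac_rows[met_index[mid]][k] = sgn * c
    rows: list[list[int]] = []
    for fr in frac_rows:
        scale = math.lcm(*(c.denominator for c in fr)) if fr else 1
        rows.append([int(c * scale) for c in fr])
    return rows, columns


def _unsplit_and_canonicalise(
    rays: Iterable[Sequence[int]],
    columns: list[tuple[int, int]],
    n_reactions: int,
    reversible_flags: Sequence[bool],
) -> list[tuple[int, ...]]:
    """Drop split two-cycles, fold split pairs back, normalise and dedupe.

    The backward copy of a reversible reaction folds in with negative sign.
    A mode whose support is entirely reversible is admissible in both
    orientations; the split cone yields both, and the canonical form keeps
    the orientation whose first nonzero flux (declaration order) is
    positive.
    """
    # which split columns belong to which reaction
    out: dict[tuple[int, ...], None] = {}
    for ray in rays:
        v = [0] * n_reactions
        for k, (j, sgn) in enumerate(columns):
            if ray[k]:
                v[j] += sgn * ray[k]
        if all(x == 0 for x in v):  # forward/backward two-cycle
            continue
        g = math.gcd(*(abs(x) for x in v))
        if g > 1:
            v = [x // g for x in v]
        if all(reversible_flags[j] for j, x in enumerate(v) if x != 0):
            first = next(x for x in v if x != 0)
            if first < 0:
                v = [-x for x in v]
        out[tuple(v)] = None
    modes = list(out)
    modes.sort(key=lambda v: (sum(1 << j for j, x in enumerate(v) if x != 0), v))
    return modes


# ---------------------------------------------------------------------------
# Double description enumeration
# ---------------------------------------------------------------------------


def _support_words(sups: list[int], n_words: int) -> np.ndarray:
    arr = np.zeros((len(sups), n_words), dtype=np.uint64)
    mask = (1 << 64) - 1
    for i, s in enumerate(sups):
        w = 0
        while s:
            arr[i, w] = s & mask
            s >>= 64
            w += 1
    return arr


def enumerate_efms(
    net: MetabolicNetwork,
    cap: int = DEFAULT_MODE_CAP,
    verify: bool = False,
) -> EfmSet:
    """Enumerate all elementary flux modes of ``net``.

    Constraints (internal metabolite rows) are processed in order of
    ascending nonzero count with the declaration index as tie-break, which
    keeps intermediate ray counts small and makes the run deterministic.
    ``cap`` bounds the intermediate ray count; exceeding it raises
    :class:`EnumerationCapExceeded` carrying partial-progress information.
    """
    t0 = time.perf_counter()
    rows, columns = split_internal_matrix(net)
    n = len(columns)
    n_words = (n + 63) // 64

    order = sorted(
        range(len(rows)), key=lambda i: (sum(1 for x in rows[i] if x), i)
    )

    rays: list[list[int]] = [[1 if k == j else 0 for k in range(n)] for j in range(n)]
    sups: list[int] = [1 << j for j in range(n)]
    max_intermediate = n

    for done, ri in enumerate(order):
        row = rows[ri]
        nz = [(k, row[k]) for k in range(n) if row[k]]
        if not nz:
            continue
        d = [sum(c * ray[k] for k, c in nz) for ray in rays]
        zi = [i for i, x in enumerate(d) if x == 0]
        pi = [i for i, x in enumerate(d) if x > 0]
        ni = [i for i, x in enumerate(d) if x < 0]
        new_rays: list[list[int]] = []
        new_sups: list[int] = []
        if pi and ni:
            words = _support_words(sups, n_words)
            n_words_arr = words  # all candidates are potential witnesses
            N_sup = words[ni]
            for p in pi:
                sp = sups[p]
                u = np.bitwise_or(words[p], N_sup)  # (len(ni), n_words)
                not_u = np.bitwise_not(u)
                # witness count per n: candidates whose support fits in u
                counts = np.zeros(len(ni), dtype=np.int64)
                chunk = max(1, 8_000_000 // max(1, len(ni) * n_words))
                for start in range(0, len(n_words_arr), chunk):
                    Cc = n_words_arr[start : start + chunk]
                    hit = (Cc[:, None, :] & not_u[None, :, :]) == 0
                    counts += hit.all(axis=2).sum(axis=0)
                rp = rays[p]
                dp = d[p]
                for pos, nn in enumerate(ni):
                    if counts[pos] != 2:  # only p and n themselves fit
                        continue
                    rn = rays[nn]
                    dn = d[nn]
                    comb = [dp * rn[k] - dn * rp[k] for k in range(n)]
                    g = math.gcd(*comb)
                    if g > 1:
                        comb = [x // g for x in comb]
                    new_rays.append(comb)
                    new_sups.append(sp | sups[nn])
        rays = [rays[i] for i in zi] + new_rays
        sups = [sups[i] for i in zi] + new_sups
        max_intermediate = max(max_intermediate, len(rays))
        if len(rays) > cap:
            raise EnumerationCapExceeded(len(rays), cap, done + 1, len(order))

    reversible_flags = [r.reversible for r in net.reactions]
    vectors = _unsplit_and_canonicalise(rays, columns, len(net.reactions), reversible_flags)
    elapsed = time.perf_counter() - t0
    efms = EfmSet(
        net,
        tuple(net.reaction_ids),
        vectors,
        elapsed_seconds=elapsed,
        stats={
            "n_split_columns": n,
            "n_constraints": len(rows),
            "max_intermediate_rays": max_intermediate,
        },
    )
    if verify:
        _verify_steady_state(efms)
    return efms


def _verify_steady_state(efms: EfmSet) -> None:
    S = efms.network.stoichiometric_matrix(internal_only=True)
    irrev = [not r.reversible for r in efms.network.reactions]
    for v in efms.vectors:
        for i in range(S.shape[0]):
            acc = sum(S[i, j] * v[j] for j in range(len(v)))
            if acc != 0:
                raise AssertionError(f"mode {v} violates steady state at row {i}")
        if any(irrev[j] and v[j] < 0 for j in range(len(v))):
            raise AssertionError(f"mode {v} runs an irreversible reaction backwards")


# ---------------------------------------------------------------------------
# Derived operations
# ---------------------------------------------------------------------------


def overall_equation(
    mode_vector: Sequence[int] | FluxMode,
    net: MetabolicNetwork,
    reaction_ids: Sequence[str] | None = None,
) -> dict[str, Fraction]:
    """Net external-metabolite equation of a mode: ``S_ext v`` (internals cancel).

    Negative entries are net consumption, positive net production; zero
    entries are omitted.
    """
    if isinstance(mode_vector, FluxMode):
        reaction_ids = mode_vector.reaction_ids
        mode_vector = mode_vector.fluxes
    rids = list(reaction_ids if reaction_ids is not None else net.reaction_ids)
    ridx = {r.id: r for r in net.reactions}
    out: dict[str, Fraction] = {}
    ext = {m.id for m in net.external_metabolites}
    for rid, v in zip(rids, mode_vector):
        if v == 0:
            continue
        for mid, c in ridx[rid].stoichiometry.items():
            if mid in ext:
                out[mid] = out.get(mid, Fraction(0)) + c * v
    return {m: c for m, c in out.items() if c != 0}


def classify_by_target(
    efms: EfmSet,
    target: str,
    carbon_sources: Iterable[str] | None = None,
) -> EfmSet:
    """Modes with strictly positive net production of ``target`` that also
    net-consume at least one designated carbon source."""
    net = efms.network
    if target not in {m.id for m in net.external_metabolites}:
        raise ValueError(f"target {target!r} is not an external metabolite")
    sources = frozenset(
        carbon_sources if carbon_sources is not None else net.config.carbon_sources
    )
    keep = []
    for i, v in enumerate(efms.vectors):
        ov = overall_equation(v, net, efms.reaction_ids)
        if ov.get(target, 0) > 0 and any(ov.get(s, 0) < 0 for s in sources):
            keep.append(i)
    return efms.subset(keep)


def knockout_filter(efms: EfmSet, removed: Iterable[str]) -> EfmSet:
    """Modes whose support avoids every removed reaction.

    Equals re-enumeration of the subnetwork without those reactions: the
    EFMs of a subnetwork are exactly the EFMs of the parent that do not use
    the deleted reactions.
    """
    removed = set(removed)
    unknown = removed - set(efms.reaction_ids)
    if unknown:
        raise ValueError(f"unknown reaction ids: {sorted(unknown)}")
    ridx = [j for j, r in enumerate(efms.reaction_ids) if r in removed]
    keep = [i for i, v in enumerate(efms.vectors) if all(v[j] == 0 for j in ridx)]
    return efms.subset(keep)


def is_affected(mode: FluxMode | frozenset[str], regulated: Iterable[str]) -> bool:
    """True iff the mode uses at least one regulated reaction."""
    support = mode.support if isinstance(mode, FluxMode) else frozenset(mode)
    return bool(support & set(regulated))


def affected_mask(efms: EfmSet, regulated: Iterable[str]) -> np.ndarray:
    regulated = set(regulated)
    ridx = [j for j, r in enumerate(efms.reaction_ids) if r in regulated]
    return np.array(
        [any(v[j] != 0 for j in ridx) for v in efms.vectors], dtype=bool
    )
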