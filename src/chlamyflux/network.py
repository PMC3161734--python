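"""Stoichiometric metabolic networks with per-metabolite carbon counts.

A network is a list of metabolites (each with a carbon-atom count and an
internal/external flag) and a list of reactions (signed rational
stoichiometry, reversibility, enzyme/gene annotation).  External metabolites
are species whose concentrations are buffered by the environment (carbon and
nitrogen sources, excreted products, CO2); they are excluded from the
steady-state constraint ``S v = 0``.

Networks are read from a small TSV dialect (one table for metabolites, one
for reactions, plus a YAML/JSON model configuration) or from SBML; the
module also houses the packaged core model of night-time nitrogen
metabolism in *Chlamydomonas reinhardtii*.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ModelConfig",
    "CarbonBalanceViolation",
    "NetworkParseError",
    "parse_reaction_table",
    "write_reaction_table",
    "validate_carbon_balance",
    "subnetwork",
    "read_sbml",
    "load_core_model",
]


class NetworkParseError(ValueError):
    """Raised when a model file does not conform to the expected dialect."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    carbon_count: int = 0
    is_external: bool = False
    skip_carbon_check: bool = False

    def __post_init__(self) -> None:
        if self.carbon_count < 0:
            raise ValueError(f"carbon_count of {self.id!r} must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """One reaction; negative coefficients are substrates, positive products."""

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    enzyme_name: str = ""
    gene_ids: tuple[str, ...] = ()
    ec_number: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r} has empty stoichiometry")
        clean = {m: Fraction(c) for m, c in self.stoichiometry.items() if c != 0}
        if not clean:
            raise ValueError(f"reaction {self.id!r} has only zero coefficients")
        object.__setattr__(self, "stoichiometry", clean)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))

    @property
    def substrates(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def equation(self) -> str:
        """Render as a human-readable equation string."""

        def side(items: dict[str, Fraction]) -> str:
            return " + ".join(f"{_fmt_coeff(c)}{m}" for m, c in items.items())

        arrow = "<->" if self.reversible else "->"
        return f"{side(self.substrates)} {arrow} {side(self.products)}"


def _fmt_coeff(c: Fraction) -> str:
    if c == 1:
        return "1 "
    if c.denominator == 1:
        return f"{c.numerator} "
    return f"{c.numerator}/{c.denominator} "


@dataclass(frozen=True)
class ModelConfig:
    """Model configuration: externals, regulation, sources and targets."""

    external: frozenset[str] = frozenset()
    regulated_reactions: frozenset[str] = frozenset()
    carbon_sources: frozenset[str] = frozenset()
    targets: tuple[str, ...] = ()

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ModelConfig":
        return cls(
            external=frozenset(raw.get("external", ())),
            regulated_reactions=frozenset(raw.get("regulated_reactions", ())),
            carbon_sources=frozenset(raw.get("carbon_sources", ())),
            targets=tuple(raw.get("targets", ())),
        )


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    name: str = ""
    config: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ValueError(f"duplicate reaction ids: {dup}")
        known = set(ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ValueError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_external]

    @property
    def external_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.is_external]

    # -- matrices --------------------------------------------------------
    def stoichiometric_matrix(self, internal_only: bool = True) -> np.ndarray:
        """S as an object-dtype array of Fractions, declaration order."""
        mets = self.internal_metabolites if internal_only else self.metabolites
        idx = {m.id: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)), dtype=object)
        S[:] = Fraction(0)
        for j, r in enumerate(self.reactions):
            for mid, c in r.stoichiometry.items():
                if mid in idx:
                    S[idx[mid], j] = c
        return S

    def with_config(self, config: ModelConfig) -> "MetabolicNetwork":
        """Re-designate externals / regulation without touching chemistry."""
        unknown = config.external - set(self.metabolite_ids)
        if unknown:
            raise ValueError(f"external ids not in network: {sorted(unknown)}")
        mets = [
            replace(m, is_external=(m.id in config.external)) for m in self.metabolites
        ]
        return MetabolicNetwork(mets, list(self.reactions), self.name, config)


# ---------------------------------------------------------------------------
# Equation / table parsing
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:/\d+)?|\d*\.\d+)\s+)?(\S+)$")


def parse_equation(eq: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``"1 A + 2 B -> 1 C"`` into signed stoichiometry + reversibility."""
    if "<->" in eq:
        sides = eq.split("<->")
        reversible = True
    elif "->" in eq:
        sides = eq.split("->")
        reversible = False
    else:
        raise NetworkParseError(f"no direction token in equation {eq!r}")
    if len(sides) != 2:
        raise NetworkParseError(f"multiple direction tokens in equation {eq!r}")
    lhs, rhs = sides
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                raise NetworkParseError(f"empty term in equation {eq!r}")
            m = _TERM_RE.match(term)
            if m is None:
                raise NetworkParseError(f"malformed term {term!r} in {eq!r}")
            coeff_s, met = m.groups()
            if met in {"+", "->", "<->"}:
                raise NetworkParseError(f"malformed term {term!r} in {eq!r}")
            coeff = Fraction(coeff_s) if coeff_s else Fraction(1)
            if coeff == 0:
                raise NetworkParseError(f"zero coefficient in {eq!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff

    add_side(lhs, -1)
    add_side(rhs, +1)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise NetworkParseError(f"equation {eq!r} cancels to nothing")
    return stoich, reversible


def _read_tsv(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: list[str] | None = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
        else:
            rows.append((lineno, fields))
    if header is None:
        raise NetworkParseError(f"{path}: empty table")
    return header, rows


def parse_metabolite_table(path: str | Path) -> list[Metabolite]:
    """Read the metabolite TSV: metabolite_id, name, carbon_count, skip_carbon_check."""
    header, rows = _read_tsv(path)
    col = {h: i for i, h in enumerate(header)}
    for required in ("metabolite_id", "carbon_count"):
        if required not in col:
            raise NetworkParseError(f"{path}: missing column {required!r}")
    mets = []
    for lineno, f in rows:
        try:
            mets.append(
                Metabolite(
                    id=f[col["metabolite_id"]].strip(),
                    name=f[col["name"]].strip() if "name" in col else "",
                    carbon_count=int(f[col["carbon_count"]]),
                    skip_carbon_check=(
                        f[col["skip_carbon_check"]].strip().lower() in {"1", "true", "yes"}
                        if "skip_carbon_check" in col and len(f) > col["skip_carbon_check"]
                        else False
                    ),
                )
            )
        except (ValueError, IndexError) as exc:
            raise NetworkParseError(f"{path}:{lineno}: {exc}") from exc
    return mets


def parse_reaction_table(
    reactions_path: str | Path,
    metabolites_path: str | Path,
    config: ModelConfig | str | Path,
    name: str = "",
) -> MetabolicNetwork:
    """Build a validated network from the reaction/metabolite TSV pair.

    The reaction table has columns ``reaction_id``, ``equation``, and
    optionally ``enzyme``, ``ec``, ``genes``; equations use ``->`` for
    irreversible and ``<->`` for reversible reactions.
    """
    if not isinstance(config, ModelConfig):
        config = ModelConfig.from_file(config)
    mets = parse_metabolite_table(metabolites_path)
    header, rows = _read_tsv(reactions_path)
    col = {h: i for i, h in enumerate(header)}
    for required in ("reaction_id", "equation"):
        if required not in col:
            raise NetworkParseError(f"{reactions_path}: missing column {required!r}")
    known = {m.id for m in mets}
    reactions: list[Reaction] = []
    seen: set[str] = set()
    for lineno, f in rows:
        rid = f[col["reaction_id"]].strip()
        if rid in seen:
            raise NetworkParseError(f"{reactions_path}:{lineno}: duplicate reaction id {rid!r}")
        seen.add(rid)
        try:
            stoich, reversible = parse_equation(f[col["equation"]])
        except NetworkParseError as exc:
            raise NetworkParseError(f"{reactions_path}:{lineno}: {exc}") from exc
        unknown = set(stoich) - known
        if unknown:
            raise NetworkParseError(
                f"{reactions_path}:{lineno}: unknown metabolite ids {sorted(unknown)}"
            )
        genes = ()
        if "genes" in col and len(f) > col["genes"] and f[col["genes"]].strip() not in {"", "-"}:
            genes = tuple(g.strip() for g in f[col["genes"]].split(",") if g.strip())
        ec = None
        if "ec" in col and len(f) > col["ec"] and f[col["ec"]].strip() not in {"", "-"}:
            ec = f[col["ec"]].strip()
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=reversible,
                enzyme_name=f[col["enzyme"]].strip() if "enzyme" in col and len(f) > col["enzyme"] else "",
                gene_ids=genes,
                ec_number=ec,
            )
        )
    net = MetabolicNetwork(mets, reactions, name=name or str(reactions_path))
    return net.with_config(config)


def write_reaction_table(
    net: MetabolicNetwork, reactions_path: str | Path, metabolites_path: str | Path
) -> None:
    """Serialise a network back to the TSV dialect (round-trips with the parser)."""
    with open(metabolites_path, "w") as fh:
        fh.write("metabolite_id\tname\tcarbon_count\tskip_carbon_check\n")
        for m in net.metabolites:
            fh.write(f"{m.id}\t{m.name}\t{m.carbon_count}\t{int(m.skip_carbon_check)}\n")
    with open(reactions_path, "w") as fh:
        fh.write("reaction_id\tequation\tenzyme\tec\tgenes\n")
        for r in net.reactions:
            fh.write(
                f"{r.id}\t{r.equation()}\t{r.enzyme_name}\t{r.ec_number or ''}\t"
                f"{','.join(r.gene_ids)}\n"
            )


# ---------------------------------------------------------------------------
# Validation and subsetting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CarbonBalanceViolation:
    reaction_id: str
    substrate_carbon: Fraction
    product_carbon: Fraction

    def __str__(self) -> str:
        return (
            f"{self.reaction_id}: {self.substrate_carbon} C in substrates vs "
            f"{self.product_carbon} C in products"
        )


def validate_carbon_balance(net: MetabolicNetwork) -> list[CarbonBalanceViolation]:
    """Report reactions whose substrate- and product-side carbon totals differ.

    Metabolites flagged ``skip_carbon_check`` (energy and redox carriers whose
    carbon moiety is conserved, e.g. ATP/NAD(P)H) are excluded from the sums.
    """
    carbon = {m.id: m.carbon_count for m in net.metabolites}
    skip = {m.id for m in net.metabolites if m.skip_carbon_check}
    out = []
    for r in net.reactions:
        sub = sum(
            (-c * carbon[m] for m, c in r.stoichiometry.items() if c < 0 and m not in skip),
            Fraction(0),
        )
        prod = sum(
            (c * carbon[m] for m, c in r.stoichiometry.items() if c > 0 and m not in skip),
            Fraction(0),
        )
        if sub != prod:
            out.append(CarbonBalanceViolation(r.id, sub, prod))
    return out


def subnetwork(
    net: MetabolicNetwork,
    drop_reactions: Iterable[str] = (),
    externals_override: Iterable[str] | None = None,
) -> MetabolicNetwork:
    """Remove reactions (and newly orphaned metabolites); optionally re-set externals."""
    drop = set(drop_reactions)
    unknown = drop - set(net.reaction_ids)
    if unknown:
        raise ValueError(f"unknown reaction ids in drop set: {sorted(unknown)}")
    reactions = [r for r in net.reactions if r.id not in drop]
    if not reactions:
        raise ValueError("subnetwork would contain no reactions")
    used = {m for r in reactions for m in r.stoichiometry}
    mets = [m for m in net.metabolites if m.id in used]
    cfg = net.config
    if externals_override is not None:
        cfg = replace(cfg, external=frozenset(externals_override) & used)
    else:
        cfg = replace(cfg, external=cfg.external & used)
    cfg = replace(
        cfg,
        regulated_reactions=cfg.regulated_reactions - drop,
        carbon_sources=cfg.carbon_sources & used,
        targets=tuple(t for t in cfg.targets if t in used),
    )
    sub = MetabolicNetwork(mets, reactions, name=f"{net.name}[-{len(drop)}rxn]")
    return sub.with_config(cfg)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------


def read_sbml(
    path: str | Path,
    carbon_counts: Mapping[str, int] | None = None,
    config: ModelConfig | None = None,
) -> MetabolicNetwork:
    """Read an SBML Level 2/3 model (species, reactions; kinetics ignored).

    ``boundaryCondition`` species become external metabolites.  SBML does not
    carry carbon counts, so they are joined in from ``carbon_counts`` (ids
    missing there get 0 and are skipped in carbon balancing).
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() and doc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise NetworkParseError(f"{path}: {doc.getError(0).getMessage()}")
    model = doc.getModel()
    if model is None:
        raise NetworkParseError(f"{path}: no model element")
    carbon_counts = carbon_counts or {}
    mets = []
    for sp in model.getListOfSpecies():
        cc = carbon_counts.get(sp.getId())
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                carbon_count=cc if cc is not None else 0,
                is_external=bool(sp.getBoundaryCondition()),
                skip_carbon_check=cc is None,
            )
        )
    reactions = []
    for rx in model.getListOfReactions():
        stoich: dict[str, Fraction] = {}
        for sr in rx.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), Fraction(0)) - Fraction(
                sr.getStoichiometry()
            ).limit_denominator(10**6)
        for sr in rx.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), Fraction(0)) + Fraction(
                sr.getStoichiometry()
            ).limit_denominator(10**6)
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            continue
        reactions.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                reversible=bool(rx.getReversible()),
                enzyme_name=rx.getName() or "",
            )
        )
    net = MetabolicNetwork(mets, reactions, name=model.getId() or str(path))
    if config is not None:
        net = net.with_config(config)
    else:
        external = frozenset(m.id for m in mets if m.is_external)
        net.config = replace(net.config, external=external)
    return net


# ---------------------------------------------------------------------------
# Packaged core model
# ---------------------------------------------------------------------------


def _data_path(fname: str):
    return resources.files("chlamyflux.data").joinpath(fname)


def load_core_model() -> MetabolicNetwork:
    """Load the packaged core model of *C. reinhardtii* night-time nitrogen
    metabolism.

    The model is a curated reduced reconstruction covering glycolysis, the
    oxidative pentose phosphate pathway, acetate activation, the citrate
    cycle with the glyoxylate shunt, nitrate/nitrite/ammonium assimilation,
    and the biosynthesis of glycine, alanine, asparagine, lysine and
    arginine, with energy and redox carriers modelled as internal species.
    Carbon sources are G6P (from night-time starch degradation) and acetate;
    the five amino acids, the nitrogen sources and CO2 are external.
    """
    with resources.as_file(_data_path("core_reactions.tsv")) as rp, resources.as_file(
        _data_path("core_metabolites.tsv")
    ) as mp, resources.as_file(_data_path("core_config.yaml")) as cp:
        return parse_reaction_table(rp, mp, cp, name="creinhardtii_nitrogen_core")


def load_core_regulation_sets() -> dict[str, frozenset[str]]:
    """Named regulated-reaction sets shipped with the core model.

    ``chlamy1`` is the full six-enzyme set; ``asl_nir_only`` restricts to the
    two enzymes with experimentally confirmed binding of the circadian
    RNA-binding factor.
    """
    with resources.as_file(_data_path("core_regulation.json")) as p:
        raw = json.loads(Path(p).read_text())
    return {k: frozenset(v) for k, v in raw.items()}
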