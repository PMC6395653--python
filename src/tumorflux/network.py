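"""Two-compartment stoichiometric network of tumor central carbon metabolism.

The model distinguishes the blood microenvironment of the tumor (a perfused
capillary compartment, metabolite ids like EGLC, LAC, ...) from a single
intracellular compartment (G6P, PYR, NADH, ...).  A network is defined in a
tab-separated text file with ``metabolite`` and ``reaction`` records (see
``data/ll2_network.tsv`` for the packaged LL/2 Lewis lung carcinoma
reconstruction: 35 enzymatic reactions over 52 metabolites), and exposes the
two stoichiometric matrices

* ``S_c`` — rows are blood metabolites, and
* ``S_m`` — rows are intracellular metabolites,

with one shared column per reaction, so that a flux vector ``r`` indexed by
reaction order drives both compartments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetworkFormatError",
    "NetworkValidationError",
    "parse_equation",
    "format_equation",
    "load_network",
    "save_network",
    "load_default_network",
    "stoichiometric_matrices",
    "to_sbml",
    "DEFAULT_NETWORK_RESOURCE",
]

COMPARTMENTS = ("blood", "cell")

#: packaged LL/2 central-carbon-metabolism reconstruction
DEFAULT_NETWORK_RESOURCE = "ll2_network.tsv"


class NetworkFormatError(ValueError):
    """Raised when a network file cannot be parsed (names line/element)."""


class NetworkValidationError(ValueError):
    """Raised when a parsed network violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species, in mM, living in exactly one compartment."""

    id: str
    name: str = ""
    compartment: str = "cell"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkValidationError(
                f"metabolite {self.id!r}: compartment must be one of "
                f"{COMPARTMENTS}, got {self.compartment!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """A (possibly lumped) enzymatic reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``drug_effects`` holds (drug_id, mode) annotations; the
    half-effect constants live with the kinetic parameters, not here.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    enzyme: str = ""
    drug_effects: tuple[tuple[str, str], ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if not np.isfinite(coef) or coef == 0:
                raise NetworkValidationError(
                    f"reaction {self.id!r}: coefficient for {met!r} must be "
                    f"finite and non-zero, got {coef!r}"
                )
        for drug, mode in self.drug_effects:
            if mode not in ("inhibit", "activate"):
                raise NetworkValidationError(
                    f"reaction {self.id!r}: drug effect mode {mode!r} for "
                    f"{drug!r} must be 'inhibit' or 'activate'"
                )

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.stoichiometry.items() if c > 0)


@dataclass
class MetabolicNetwork:
    """Validated two-compartment network with cached stoichiometric matrices."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str = "Vgrowth"
    _S_c: np.ndarray = field(init=False, repr=False, default=None)
    _S_m: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.validate()
        # cached index structures (the network is immutable after loading)
        self._blood_ids = [m.id for m in self.metabolites
                           if m.compartment == "blood"]
        self._cell_ids = [m.id for m in self.metabolites
                          if m.compartment == "cell"]
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}

    # -- index helpers -----------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def blood_ids(self) -> list[str]:
        return self._blood_ids

    @property
    def cell_ids(self) -> list[str]:
        return self._cell_ids

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        met_ids = self.metabolite_ids
        dup = {i for i in met_ids if met_ids.count(i) > 1}
        if dup:
            raise NetworkValidationError(f"duplicate metabolite id(s): {sorted(dup)}")
        rxn_ids = self.reaction_ids
        dup = {i for i in rxn_ids if rxn_ids.count(i) > 1}
        if dup:
            raise NetworkValidationError(f"duplicate reaction id(s): {sorted(dup)}")
        known = set(met_ids)
        dangling = {
            m for r in self.reactions for m in r.stoichiometry if m not in known
        }
        if dangling:
            raise NetworkValidationError(
                f"reaction(s) reference undeclared metabolite(s): {sorted(dangling)}"
            )
        if self.biomass_id not in rxn_ids:
            raise NetworkValidationError(
                f"biomass reaction {self.biomass_id!r} not present"
            )

    # -- stoichiometry -----------------------------------------------------
    def _build_matrices(self) -> None:
        n_r = len(self.reactions)
        blood, cell = self.blood_ids, self.cell_ids
        S_c = np.zeros((len(blood), n_r))
        S_m = np.zeros((len(cell), n_r))
        b_index = {m: i for i, m in enumerate(blood)}
        c_index = {m: i for i, m in enumerate(cell)}
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                if met in b_index:
                    S_c[b_index[met], j] = coef
                else:
                    S_m[c_index[met], j] = coef
        self._S_c, self._S_m = S_c, S_m

    @property
    def S_c(self) -> np.ndarray:
        if self._S_c is None:
            self._build_matrices()
        return self._S_c

    @property
    def S_m(self) -> np.ndarray:
        if self._S_m is None:
            self._build_matrices()
        return self._S_m


# ---------------------------------------------------------------------------
# equation strings
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``"1 A + 2 B -> 1 C"`` (or ``<->``) into (stoichiometry, reversible).

    An empty side denotes exchange with the outside (source/sink).
    """
    if "<->" in eq:
        lhs, rhs = eq.split("<->", 1)
        reversible = True
    elif "->" in eq:
        lhs, rhs = eq.split("->", 1)
        reversible = False
    else:
        raise NetworkFormatError(f"equation {eq!r}: missing '->' or '<->'")
    stoich: dict[str, float] = {}

    def add(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            m = _TERM_RE.match(term)
            if m is None:
                raise NetworkFormatError(f"equation {eq!r}: bad term {term!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add(lhs, -1)
    add(rhs, +1)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    return stoich, reversible


def _fmt_coef(c: float) -> str:
    return f"{c:g}"


def format_equation(rxn: Reaction) -> str:
    lhs = " + ".join(
        f"{_fmt_coef(-c)} {m}" for m, c in rxn.stoichiometry.items() if c < 0
    )
    rhs = " + ".join(
        f"{_fmt_coef(c)} {m}" for m, c in rxn.stoichiometry.items() if c > 0
    )
    arrow = "<->" if rxn.reversible else "->"
    return f"{lhs} {arrow} {rhs}".strip()


# ---------------------------------------------------------------------------
# TSV dialect (source of truth)
# ---------------------------------------------------------------------------


def load_network(path: str | Path, biomass_id: str = "Vgrowth") -> MetabolicNetwork:
    """Load a network from the tabular dialect; deterministic file order."""
    path = Path(path)
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0].strip()
            try:
                if kind == "metabolite":
                    _, mid, name, comp = (fields + [""] * 4)[:4]
                    metabolites.append(
                        Metabolite(mid.strip(), name.strip(), comp.strip())
                    )
                elif kind == "reaction":
                    _, rid, eq, rev, enzyme, drugs, notes = (fields + [""] * 7)[:7]
                    stoich, eq_rev = parse_equation(eq)
                    reversible = bool(int(rev)) if rev.strip() else eq_rev
                    effects = tuple(
                        tuple(p.strip() for p in pair.split(":", 1))
                        for pair in drugs.split(";")
                        if pair.strip()
                    )
                    reactions.append(
                        Reaction(
                            rid.strip(),
                            stoich,
                            reversible=reversible,
                            enzyme=enzyme.strip(),
                            drug_effects=effects,  # type: ignore[arg-type]
                            notes=notes.strip(),
                        )
                    )
                else:
                    raise NetworkFormatError(
                        f"unknown record type {kind!r}"
                    )
            except NetworkFormatError as err:
                raise NetworkFormatError(f"{path}:{lineno}: {err}") from None
    return MetabolicNetwork(metabolites, reactions, biomass_id=biomass_id)


def save_network(net: MetabolicNetwork, path: str | Path) -> None:
    """Serialize back to the tabular dialect (round-trips with load_network)."""
    lines = ["# tumorflux network file"]
    for m in net.metabolites:
        lines.append(f"metabolite\t{m.id}\t{m.name}\t{m.compartment}")
    for r in net.reactions:
        drugs = ";".join(f"{d}:{mode}" for d, mode in r.drug_effects)
        lines.append(
            f"reaction\t{r.id}\t{format_equation(r)}\t{int(r.reversible)}"
            f"\t{r.enzyme}\t{drugs}\t{r.notes}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_default_network() -> MetabolicNetwork:
    """The packaged LL/2 reconstruction (35 reactions, 52 metabolites)."""
    ref = resources.files("tumorflux.data").joinpath(DEFAULT_NETWORK_RESOURCE)
    with resources.as_file(ref) as p:
        return load_network(p)


def stoichiometric_matrices(net: MetabolicNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(S_c, S_m)``: blood and intracellular stoichiometric matrices."""
    return net.S_c, net.S_m


# ---------------------------------------------------------------------------
# SBML export (interoperability; the TSV dialect remains the source of truth)
# ---------------------------------------------------------------------------


def to_sbml(net: MetabolicNetwork, path: str | Path) -> None:
    """Write the network as SBML via cobra for third-party tools."""
    import cobra

    model = cobra.Model("tumorflux")
    # blood is the extracellular/external compartment ("e" by convention)
    comp_map = {"blood": "e", "cell": "c"}
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=comp_map[m.compartment])
        for m in net.metabolites
    }
    for r in net.reactions:
        rx = cobra.Reaction(r.id, name=r.enzyme or r.id)
        rx.lower_bound = -1000.0 if r.reversible else 0.0
        rx.upper_bound = 1000.0
        rx.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        model.add_reactions([rx])
    # blood species exchange freely with the body; mark them boundary
    for m in net.metabolites:
        if m.compartment == "blood":
            model.add_boundary(mets[m.id], type="exchange")
    cobra.io.write_sbml_model(model, str(path))
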