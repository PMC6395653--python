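"""Rate laws and drug-modulated flux computation.

Each reaction carries a generalized multiplicative Michaelis–Menten law

    v = f_drug * [ vmax * prod_s c_s/(K_s + c_s)  -  vmax_rev * prod_p c_p/(K_p + c_p) ]

where the forward product runs over substrates (and kinetic effectors) with a
K entry and the reverse product over products with a K entry; irreversible
reactions have ``vmax_rev = 0``.  Drug action is multiplicative and
non-competitive in style: an inhibitor at concentration d scales its target
by k/(k+d) in (0, 1], an activator by 1 + d/(k+d) in [1, 2).  The four drugs
of the therapy map onto five targets: diclofenac inhibits VHK and VLDH,
alpha-lipoic acid activates VPDH, hydroxycitrate inhibits VACL, and metformin
inhibits VATPase while activating the NAD leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .network import MetabolicNetwork, load_default_network

__all__ = [
    "RateLaw",
    "DrugEffect",
    "KineticModel",
    "modulation_factor",
    "reaction_rate",
    "flux_vector",
    "ParameterSet",
    "load_parameters",
    "load_default_parameters",
    "load_default_model",
    "DRUG_IDS",
    "DEFAULT_PARAMETERS_RESOURCE",
]

DRUG_IDS = ("DICLO", "LA", "HCIT", "METF")

DEFAULT_PARAMETERS_RESOURCE = "ll2_parameters.tsv"


@dataclass(frozen=True)
class RateLaw:
    """Michaelis–Menten parameters for one reaction.

    ``km`` maps species id to a half-saturation constant (mM); keys that are
    neither substrate nor product act as forward kinetic effectors.
    """

    reaction_id: str
    vmax: float
    km: dict[str, float] = field(default_factory=dict)
    vmax_rev: float = 0.0

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError(f"{self.reaction_id}: vmax must be >= 0")
        if self.vmax_rev < 0:
            raise ValueError(f"{self.reaction_id}: vmax_rev must be >= 0")
        for s, k in self.km.items():
            if k <= 0:
                raise ValueError(f"{self.reaction_id}: km[{s}] must be > 0")


@dataclass(frozen=True)
class DrugEffect:
    """One drug/target annotation with its half-effect concentration (mM)."""

    drug_id: str
    target_reaction_id: str
    mode: str  # "inhibit" | "activate"
    k_half: float

    def __post_init__(self) -> None:
        if self.mode not in ("inhibit", "activate"):
            raise ValueError(f"mode must be inhibit/activate, got {self.mode!r}")
        if self.k_half <= 0:
            raise ValueError("k_half must be > 0")


def modulation_factor(effect: DrugEffect, drug_conc: float) -> float:
    """Dimensionless drug factor; exactly 1 at zero concentration."""
    if drug_conc < 0:
        raise ValueError(f"drug concentration must be >= 0, got {drug_conc}")
    if effect.mode == "inhibit":
        return effect.k_half / (effect.k_half + drug_conc)
    return 1.0 + drug_conc / (effect.k_half + drug_conc)


def reaction_rate(
    law: RateLaw,
    conc: dict[str, float],
    factors: float = 1.0,
    substrates: tuple[str, ...] = (),
    products: tuple[str, ...] = (),
) -> float:
    """Evaluate one rate law at the given concentrations (mM).

    ``substrates``/``products`` identify which km entries belong to the
    reverse term; km keys outside both sets are forward effectors.
    """
    fwd = law.vmax
    rev = law.vmax_rev
    prod_set = set(products)
    for sp, k in law.km.items():
        if sp not in conc:
            raise KeyError(
                f"{law.reaction_id}: no concentration provided for {sp!r}"
            )
        c = max(conc[sp], 0.0)
        sat = c / (k + c)
        if sp in prod_set:
            rev *= sat
        else:
            fwd *= sat
    return factors * (fwd - rev)


@dataclass
class KineticModel:
    """A network plus one rate law per reaction and the drug-effect table."""

    network: MetabolicNetwork
    rate_laws: dict[str, RateLaw]
    drug_effects: list[DrugEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        rxn_ids = set(self.network.reaction_ids)
        missing = rxn_ids - set(self.rate_laws)
        if missing:
            raise ValueError(f"reactions without a rate law: {sorted(missing)}")
        extra = set(self.rate_laws) - rxn_ids
        if extra:
            raise ValueError(f"rate laws for unknown reactions: {sorted(extra)}")
        for law in self.rate_laws.values():
            rxn = self.network.reaction(law.reaction_id)
            if law.vmax_rev > 0 and not rxn.reversible:
                raise ValueError(
                    f"{law.reaction_id}: vmax_rev > 0 on an irreversible reaction"
                )
        for eff in self.drug_effects:
            if eff.target_reaction_id not in rxn_ids:
                raise ValueError(
                    f"drug effect targets unknown reaction "
                    f"{eff.target_reaction_id!r}"
                )
        self._compiled = None

    # -- compiled fast path ------------------------------------------------
    def _compile(self) -> None:
        """Precompute index arrays so flux evaluation is fully vectorized."""
        net = self.network
        order = net.blood_ids + net.cell_ids
        self._species_index = {s: i for i, s in enumerate(order)}
        n_r = len(net.reactions)
        pair_rxn, pair_sp, pair_km, pair_rev = [], [], [], []
        vmax = np.zeros(n_r)
        vmax_rev = np.zeros(n_r)
        for j, rxn in enumerate(net.reactions):
            law = self.rate_laws[rxn.id]
            vmax[j] = law.vmax
            vmax_rev[j] = law.vmax_rev
            prods = set(rxn.products)
            for sp, k in law.km.items():
                pair_rxn.append(j)
                pair_sp.append(self._species_index[sp])
                pair_km.append(k)
                pair_rev.append(sp in prods)
        self._pair_rxn = np.asarray(pair_rxn, dtype=np.intp)
        self._pair_sp = np.asarray(pair_sp, dtype=np.intp)
        self._pair_km = np.asarray(pair_km)
        self._pair_rev = np.asarray(pair_rev, dtype=bool)
        self._vmax = vmax
        self._vmax_rev = vmax_rev
        # segment layout for product-by-reaction via multiply.reduceat:
        # pairs are emitted grouped by reaction, so fwd/rev subsets stay
        # grouped; empty segments are padded with a sentinel 1.0 term
        def segments(mask):
            rxn = self._pair_rxn[mask]
            sp = self._pair_sp[mask]
            km = self._pair_km[mask]
            counts = np.bincount(rxn, minlength=n_r)
            widths = np.maximum(counts, 1)  # empty segments hold one 1.0
            seg_starts = np.zeros(n_r, dtype=np.intp)
            np.cumsum(widths[:-1], out=seg_starts[1:])
            # slot of each pair inside the padded array (pairs are grouped
            # and ordered by reaction)
            within = np.arange(rxn.size) - np.concatenate(
                ([0], np.cumsum(counts)[:-1])
            )[rxn]
            slots = seg_starts[rxn] + within
            return sp, km, slots, seg_starts, int(widths.sum())

        self._fwd_layout = segments(~self._pair_rev)
        self._rev_layout = segments(self._pair_rev)
        # drug effects grouped per target column
        self._effects = [
            (self._species_index.get(e.drug_id),  # drug may be a blood species
             e, net.reaction_index(e.target_reaction_id))
            for e in self.drug_effects
        ]
        self._compiled = True

    def drug_factors(self, doses: dict[str, float] | None) -> np.ndarray:
        """Per-reaction product of modulation factors for the given doses (mM)."""
        if self._compiled is None:
            self._compile()
        factors = np.ones(len(self.network.reactions))
        if not doses:
            return factors
        for _, eff, j in self._effects:
            d = doses.get(eff.drug_id, 0.0)
            if d:
                factors[j] *= modulation_factor(eff, d)
        return factors

    def fluxes(self, concentrations: np.ndarray, doses=None) -> np.ndarray:
        """Flux vector r from the stacked [blood; cell] concentration vector."""
        if self._compiled is None:
            self._compile()

        def products(layout):
            sp, km, slots, seg_starts, total = layout
            if sp.size == 0:
                return 1.0
            c = np.maximum(concentrations[sp], 0.0)
            padded = np.ones(total)
            padded[slots] = c / (km + c)
            return np.multiply.reduceat(padded, seg_starts)

        fwd = self._vmax * products(self._fwd_layout)
        rev = self._vmax_rev * products(self._rev_layout)
        return self.drug_factors(doses) * (fwd - rev)


def flux_vector(
    model: KineticModel,
    m: np.ndarray | dict[str, float],
    C: np.ndarray | dict[str, float],
    doses: dict[str, float] | None = None,
) -> np.ndarray:
    """Flux vector r (network reaction order) at state (m, C) and drug doses.

    ``m`` is indexed by the network's intracellular metabolite order, ``C`` by
    its blood order; dicts keyed by metabolite id are also accepted.  When
    ``doses`` is omitted, drug concentrations present in ``C`` (the drugs are
    blood species, supplied with the inlet flow) are used.
    """
    net = model.network
    if isinstance(C, dict):
        C = np.array([C.get(s, 0.0) for s in net.blood_ids])
    if isinstance(m, dict):
        m = np.array([m.get(s, 0.0) for s in net.cell_ids])
    C = np.asarray(C, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(C < 0) or np.any(m < 0):
        raise ValueError("concentrations must be non-negative")
    if doses is None:
        blood_index = {s: i for i, s in enumerate(net.blood_ids)}
        doses = {
            d: float(C[blood_index[d]]) for d in DRUG_IDS if d in blood_index
        }
    return model.fluxes(np.concatenate([C, m]), doses)


# ---------------------------------------------------------------------------
# parameter file I/O
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Contents of a parameter file: rate laws, drug table, default state."""

    rate_laws: dict[str, RateLaw]
    drug_effects: list[DrugEffect]
    inlet: dict[str, float] = field(default_factory=dict)   # C0, mM
    init_cell: dict[str, float] = field(default_factory=dict)  # m(t0), mM
    init_blood: dict[str, float] = field(default_factory=dict)  # C(t0) overrides


def load_parameters(path: str | Path) -> ParameterSet:
    """Parse the TSV parameter dialect (rate/drug/inlet/init records)."""
    params = ParameterSet({}, [])
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0].strip()
            try:
                if kind == "rate":
                    _, rid, vmax, vrev, kms = (fields + [""] * 5)[:5]
                    km = {}
                    for pair in kms.split(";"):
                        if pair.strip():
                            sp, val = pair.split(":")
                            km[sp.strip()] = float(val)
                    params.rate_laws[rid.strip()] = RateLaw(
                        rid.strip(), float(vmax), km, float(vrev or 0)
                    )
                elif kind == "drug":
                    _, drug, target, mode, khalf = (fields + [""] * 5)[:5]
                    params.drug_effects.append(
                        DrugEffect(drug.strip(), target.strip(), mode.strip(),
                                   float(khalf))
                    )
                elif kind == "inlet":
                    _, sp, val = (fields + [""] * 3)[:3]
                    params.inlet[sp.strip()] = float(val)
                elif kind == "init":
                    _, sp, val = (fields + [""] * 3)[:3]
                    params.init_cell[sp.strip()] = float(val)
                elif kind == "cinit":
                    _, sp, val = (fields + [""] * 3)[:3]
                    params.init_blood[sp.strip()] = float(val)
                else:
                    raise ValueError(f"unknown record type {kind!r}")
            except (ValueError, KeyError) as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
    return params


def load_default_parameters() -> ParameterSet:
    ref = resources.files("tumorflux.data").joinpath(DEFAULT_PARAMETERS_RESOURCE)
    with resources.as_file(ref) as p:
        return load_parameters(p)


def load_default_model(network: MetabolicNetwork | None = None) -> KineticModel:
    """Packaged LL/2 model with calibrated default parameters."""
    net = network if network is not None else load_default_network()
    params = load_default_parameters()
    return KineticModel(net, params.rate_laws, params.drug_effects)
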