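"""Mass-action reaction networks: data model, text format, validation, rate laws.

A network is a set of aqueous species and elementary reactions with
mass-action kinetics.  Species may be *clamped* (held at a fixed
concentration during integration — used for H+ under pH buffering and for
air-saturated dissolved O2), in which case their time derivative is forced
to zero while they still participate in rate laws.

Concentrations are mol L-1 throughout; rate constants are s-1 for
unimolecular, L mol-1 s-1 for bimolecular and L2 mol-2 s-1 for termolecular
steps.  Fractional product yields are expressed by splitting a reaction into
parallel integer-stoichiometry channels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Mapping, Optional

import numpy as np


class NetworkError(ValueError):
    """Raised for malformed or inconsistent reaction networks."""


class ParseError(NetworkError):
    """Raised when a network document does not follow the grammar."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species.

    ``charge`` is informational only; no charge balance is enforced.
    ``clamped`` species keep their initial concentration for the whole
    integration (their net derivative is zeroed).
    """

    name: str
    charge: int = 0
    clamped: bool = False
    initial_conc: float = 0.0

    def __post_init__(self):
        if not self.name or any(ch.isspace() for ch in self.name):
            raise NetworkError(f"invalid species name {self.name!r}")
        if self.initial_conc < 0:
            raise NetworkError(
                f"species {self.name}: initial concentration must be >= 0, "
                f"got {self.initial_conc}"
            )


@dataclass(frozen=True)
class ReactionSpec:
    """One elementary mass-action reaction.

    ``channel`` is a free-form tag consumed by flux attribution (e.g.
    "direct_metal", "OH", "NQN12"); ``source`` is a citation tag.
    """

    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float
    channel: str = ""
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))
        if not self.id or any(ch.isspace() for ch in self.id):
            raise NetworkError(f"invalid reaction id {self.id!r}")
        if self.rate_constant <= 0:
            raise NetworkError(
                f"reaction {self.id}: rate constant must be > 0, "
                f"got {self.rate_constant}"
            )
        for side, coeffs in (("reactant", self.reactants), ("product", self.products)):
            for sp, nu in coeffs.items():
                if int(nu) != nu or nu <= 0:
                    raise NetworkError(
                        f"reaction {self.id}: {side} stoichiometry for {sp} "
                        f"must be a positive integer, got {nu}"
                    )
        order = sum(self.reactants.values())
        if order not in (1, 2, 3):
            raise NetworkError(
                f"reaction {self.id}: total reactant order must be 1, 2 or 3, "
                f"got {order}"
            )

    @property
    def order(self) -> int:
        return sum(self.reactants.values())

    def net_stoichiometry(self, species: str) -> int:
        return self.products.get(species, 0) - self.reactants.get(species, 0)


@dataclass
class NetworkSpec:
    """A validated set of species and reactions."""

    species: List[SpeciesSpec] = field(default_factory=list)
    reactions: List[ReactionSpec] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        self.validate()

    # -- bookkeeping -------------------------------------------------------

    @property
    def species_names(self) -> List[str]:
        return [s.name for s in self.species]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def species_index(self) -> Dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def get_species(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_conc for s in self.species], dtype=float)

    def validate(self) -> None:
        names = self.species_names
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NetworkError(f"duplicate species names: {', '.join(dup)}")
        ids = self.reaction_ids
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate reaction ids: {', '.join(dup)}")
        declared = set(names)
        for r in self.reactions:
            for sp in list(r.reactants) + list(r.products):
                if sp not in declared:
                    raise NetworkError(
                        f"reaction {r.id} references undeclared species {sp!r}"
                    )

    # -- edits (return new objects; NetworkSpec itself stays mutable-light) --

    def with_initial(self, **conc: float) -> "NetworkSpec":
        """Return a copy with selected initial concentrations replaced."""
        idx = self.species_index()
        for name in conc:
            if name not in idx:
                raise NetworkError(f"unknown species {name!r}")
        species = [
            replace(s, initial_conc=conc.get(s.name, s.initial_conc))
            for s in self.species
        ]
        return NetworkSpec(species=species, reactions=list(self.reactions),
                           name=self.name)

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry, shape (n_species, n_reactions)."""
        idx = self.species_index()
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sp, nu in r.reactants.items():
                S[idx[sp], j] -= nu
            for sp, nu in r.products.items():
                S[idx[sp], j] += nu
        return S

    # -- tabular export ----------------------------------------------------

    def reactions_frame(self):
        import pandas as pd

        rows = []
        for r in self.reactions:
            rows.append(
                {
                    "id": r.id,
                    "reactants": _side_to_text(r.reactants),
                    "products": _side_to_text(r.products),
                    "k": r.rate_constant,
                    "channel": r.channel,
                    "source": r.source,
                }
            )
        return pd.DataFrame(rows, columns=["id", "reactants", "products", "k",
                                           "channel", "source"])

    def species_frame(self):
        import pandas as pd

        rows = [
            {"name": s.name, "charge": s.charge, "clamped": s.clamped,
             "initial_conc": s.initial_conc}
            for s in self.species
        ]
        return pd.DataFrame(rows, columns=["name", "charge", "clamped",
                                           "initial_conc"])


def merge_networks(*nets: NetworkSpec, name: str = "") -> NetworkSpec:
    """Merge networks/fragments with set semantics on reaction ids.

    Species occurring in several fragments must agree on clamping; the
    largest initial concentration wins (fragments usually declare zero and
    scenario compilation fills values in).  Merging is order-independent.
    """
    species: Dict[str, SpeciesSpec] = {}
    reactions: Dict[str, ReactionSpec] = {}
    for net in nets:
        for s in net.species:
            if s.name in species:
                prev = species[s.name]
                if prev.clamped != s.clamped:
                    raise NetworkError(
                        f"species {s.name}: inconsistent clamp flag across fragments"
                    )
                species[s.name] = replace(
                    prev, initial_conc=max(prev.initial_conc, s.initial_conc)
                )
            else:
                species[s.name] = s
        for r in net.reactions:
            if r.id in reactions:
                if reactions[r.id] != r:
                    raise NetworkError(
                        f"reaction id {r.id} defined twice with different bodies"
                    )
            else:
                reactions[r.id] = r
    return NetworkSpec(
        species=[species[k] for k in sorted(species)],
        reactions=[reactions[k] for k in sorted(reactions)],
        name=name or "+".join(n.name for n in nets if n.name),
    )


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def reaction_flux(r: ReactionSpec, conc: Mapping[str, float]) -> float:
    """Elementary mass-action flux, mol L-1 s-1.

    flux = k * prod(reactant conc ** stoichiometry).  Zero if any reactant
    is absent; negative concentrations are a domain error.
    """
    flux = r.rate_constant
    for sp, nu in r.reactants.items():
        c = conc[sp]
        if c < 0:
            raise NetworkError(
                f"reaction {r.id}: negative concentration for {sp} ({c})"
            )
        flux *= c ** nu
    return flux


def assemble_rhs(net: NetworkSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Compile the ODE right-hand side d[s]/dt for a validated network.

    Returns ``rhs(y) -> dy`` on the species state vector (ordering of
    ``net.species``).  Clamped species get a zero derivative.  The returned
    callable also exposes ``rhs.fluxes(y)`` giving per-reaction fluxes, which
    the simulator uses to integrate cumulative extents.
    """
    net.validate()
    idx = net.species_index()
    S = net.stoichiometry_matrix()
    clamped = np.array([s.clamped for s in net.species], dtype=bool)

    # flatten reactant lists: repeated index <=> higher stoichiometry
    r_indices: List[np.ndarray] = []
    ks = np.array([r.rate_constant for r in net.reactions], dtype=float)
    for r in net.reactions:
        ii: List[int] = []
        for sp, nu in r.reactants.items():
            ii.extend([idx[sp]] * nu)
        r_indices.append(np.array(ii, dtype=int))

    n_rx = len(net.reactions)

    def fluxes(y: np.ndarray) -> np.ndarray:
        f = ks.copy()
        for j in range(n_rx):
            f[j] *= np.prod(y[r_indices[j]])
        return f

    def rhs(y: np.ndarray) -> np.ndarray:
        dy = S @ fluxes(y)
        dy[clamped] = 0.0
        return dy

    rhs.fluxes = fluxes  # type: ignore[attr-defined]
    rhs.stoichiometry = S  # type: ignore[attr-defined]
    rhs.clamped = clamped  # type: ignore[attr-defined]
    return rhs


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------
#
# Line-oriented, UTF-8.  Example:
#
#     network fenton_demo
#     species:
#       Fe2+   charge=2  init=1e-6
#       H+     charge=1  init=1.58e-7  clamped
#       H2O2   init=1e-6
#     reactions:
#       R1: Fe2+ + H2O2 -> Fe3+ + OH + OH- : k = 55 ; channel = OH ; source = lit
#       R2: 2 A.- -> DHA + AH- : k = 2e5 ; channel = disproportionation
#
# '#' starts a comment.  Stoichiometric coefficients are integer prefixes.

_SPECIES_RE = re.compile(r"^(?P<name>\S+)(?P<rest>(\s+\S+)*)\s*$")
_TERM_RE = re.compile(r"^(?:(?P<coef>\d+)\s+)?(?P<name>\S+)$")


def _parse_side(text: str, line_no: int) -> Dict[str, int]:
    # terms are separated by whitespace-delimited '+', so ion names like
    # Fe2+ or OH- survive
    coeffs: Dict[str, int] = {}
    for term in re.split(r"\s+\+\s+", text.strip()):
        term = term.strip()
        if not term:
            raise ParseError("empty term in reaction side", line_no)
        m = _TERM_RE.match(term)
        if not m:
            raise ParseError(f"cannot parse reaction term {term!r}", line_no)
        nu = int(m.group("coef") or 1)
        name = m.group("name")
        coeffs[name] = coeffs.get(name, 0) + nu
    return coeffs


def parse_network(text: str) -> NetworkSpec:
    """Parse the documented structured-text dialect into a NetworkSpec.

    Raises :class:`ParseError` (with line number) for grammar violations and
    :class:`NetworkError` for semantic ones (undeclared species, bad rate
    constants, duplicate ids).
    """
    name = ""
    species: List[SpeciesSpec] = []
    reactions: List[ReactionSpec] = []
    rx_lines: Dict[str, int] = {}
    section = None
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        stripped = line.strip()
        if stripped.startswith("network"):
            name = stripped[len("network"):].strip()
            continue
        if stripped == "species:":
            section = "species"
            continue
        if stripped == "reactions:":
            section = "reactions"
            continue
        if section == "species":
            m = _SPECIES_RE.match(stripped)
            if not m:
                raise ParseError(f"cannot parse species line {stripped!r}", line_no)
            sp_name = m.group("name")
            charge = 0
            clamped = False
            init = 0.0
            for tok in m.group("rest").split():
                if tok == "clamped":
                    clamped = True
                elif tok.startswith("charge="):
                    charge = int(tok.split("=", 1)[1])
                elif tok.startswith("init="):
                    init = float(tok.split("=", 1)[1])
                else:
                    raise ParseError(f"unknown species attribute {tok!r}", line_no)
            try:
                species.append(SpeciesSpec(sp_name, charge, clamped, init))
            except NetworkError as exc:
                raise ParseError(str(exc), line_no) from exc
        elif section == "reactions":
            try:
                head, body = stripped.split(":", 1)
            except ValueError:
                raise ParseError(f"reaction line needs 'ID: ...': {stripped!r}",
                                 line_no)
            rid = head.strip()
            parts = [p.strip() for p in body.split(";")]
            eq = parts[0]
            if "->" not in eq:
                raise ParseError("reaction needs '->'", line_no)
            eq_part, _, k_part = eq.partition(":")
            if not k_part.strip():
                raise ParseError("reaction needs ': k = <value>'", line_no)
            lhs, rhs_text = eq_part.split("->", 1)
            km = re.match(r"^k\s*=\s*(?P<k>\S+)$", k_part.strip())
            if not km:
                raise ParseError(f"cannot parse rate constant {k_part.strip()!r}",
                                 line_no)
            channel = ""
            source = ""
            for extra in parts[1:]:
                if not extra:
                    continue
                key, _, val = extra.partition("=")
                key, val = key.strip(), val.strip()
                if key == "channel":
                    channel = val
                elif key == "source":
                    source = val
                else:
                    raise ParseError(f"unknown reaction attribute {key!r}", line_no)
            rx_lines.setdefault(rid, line_no)
            try:
                reactions.append(
                    ReactionSpec(
                        id=rid,
                        reactants=_parse_side(lhs, line_no),
                        products=_parse_side(rhs_text, line_no),
                        rate_constant=float(km.group("k")),
                        channel=channel,
                        source=source,
                    )
                )
            except NetworkError as exc:
                raise ParseError(str(exc), line_no) from exc
        else:
            raise ParseError(f"content outside species/reactions block: {stripped!r}",
                             line_no)

    try:
        return NetworkSpec(species=species, reactions=reactions, name=name)
    except NetworkError as exc:
        # attach the offending line to undeclared-species / duplicate-id errors
        m = re.search(r"reaction (\S+) ", str(exc))
        line = rx_lines.get(m.group(1)) if m else None
        raise ParseError(str(exc), line) from exc


def _side_to_text(coeffs: Mapping[str, int]) -> str:
    terms = []
    for sp, nu in coeffs.items():
        terms.append(f"{nu} {sp}" if nu != 1 else sp)
    return " + ".join(terms)


def serialize_network(net: NetworkSpec) -> str:
    """Emit the same dialect :func:`parse_network` reads (round-trips)."""
    lines = []
    if net.name:
        lines.append(f"network {net.name}")
    lines.append("species:")
    for s in net.species:
        attrs = []
        if s.charge:
            attrs.append(f"charge={s.charge}")
        attrs.append(f"init={s.initial_conc:.10g}")
        if s.clamped:
            attrs.append("clamped")
        lines.append(f"  {s.name}  " + "  ".join(attrs))
    lines.append("reactions:")
    for r in net.reactions:
        rec = (f"  {r.id}: {_side_to_text(r.reactants)} -> "
               f"{_side_to_text(r.products)} : k = {r.rate_constant:.10g}")
        if r.channel:
            rec += f" ; channel = {r.channel}"
        if r.source:
            rec += f" ; source = {r.source}"
        lines.append(rec)
    return "\n".join(lines) + "\n"
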