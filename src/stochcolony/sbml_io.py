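"""SBML Level 3 Version 1 serialisation of the mass-action model subset.

The writer emits one compartment of size 1, species with integer initial
*amounts* (counts, not concentrations — unambiguous for stochastic
simulation), and reactions carrying a mass-action kinetic law
``k * reactant_1 * ... * reactant_m`` with a local parameter ``k``.

The reader accepts exactly this dialect and rejects anything else with an
error naming the offending element.  Arbitrary BioModels documents are out
of scope by design; the supported subset is the closure of what
:func:`stochcolony.crn.build_serial_pathway` produces.
"""

from __future__ import annotations

import os
from pathlib import Path

from lxml import etree

from .crn import CRNModel, Reaction, Species

__all__ = ["write_sbml", "read_sbml", "SBMLParseError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_S = "{%s}" % SBML_NS
_M = "{%s}" % MATHML_NS


class SBMLParseError(ValueError):
    """Raised when a document is not in the supported SBML subset."""


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def write_sbml(model: CRNModel, path: str | os.PathLike) -> Path:
    """Write ``model`` as an SBML L3V1 document; returns the path written."""
    model.validate()

    root = etree.Element(_S + "sbml", nsmap={None: SBML_NS})
    root.set("level", "3")
    root.set("version", "1")
    mdl = etree.SubElement(root, _S + "model", id=model.name)

    comps = etree.SubElement(mdl, _S + "listOfCompartments")
    etree.SubElement(
        comps, _S + "compartment", id="cell", size="1", spatialDimensions="3",
        constant="true",
    )

    sp_list = etree.SubElement(mdl, _S + "listOfSpecies")
    for sp in model.species:
        etree.SubElement(
            sp_list, _S + "species",
            id=sp.id,
            compartment="cell",
            initialAmount=_fmt(sp.initial_count),
            hasOnlySubstanceUnits="true",
            boundaryCondition="false",
            constant="false",
        )

    rxn_list = etree.SubElement(mdl, _S + "listOfReactions")
    for rxn in model.reactions:
        r_el = etree.SubElement(
            rxn_list, _S + "reaction", id=rxn.id, reversible="false", fast="false"
        )
        for tag, pairs in (
            ("listOfReactants", rxn.reactants),
            ("listOfProducts", rxn.products),
        ):
            lst = etree.SubElement(r_el, _S + tag)
            for sid, stoich in pairs:
                etree.SubElement(
                    lst, _S + "speciesReference",
                    species=sid, stoichiometry=str(int(stoich)), constant="true",
                )
        kl = etree.SubElement(r_el, _S + "kineticLaw")
        math = etree.SubElement(kl, _M + "math", nsmap={None: MATHML_NS})
        apply_el = etree.SubElement(math, _M + "apply")
        etree.SubElement(apply_el, _M + "times")
        for name in ("k", *(sid for sid, _ in rxn.reactants)):
            ci = etree.SubElement(apply_el, _M + "ci")
            ci.text = f" {name} "
        params = etree.SubElement(kl, _S + "listOfLocalParameters")
        etree.SubElement(params, _S + "localParameter", id="k", value=_fmt(rxn.k))

    path = Path(path)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)
    return path


def _infer_roles_and_topology(
    species_ids: list[str], reactions: list[Reaction]
) -> tuple[dict[str, str], str]:
    """Catalysts (appear on both sides of a reaction) are enzymes.

    One catalyst shared by every reaction -> single_enz (for n >= 2; a
    1-reaction pathway is tagged multi_enz since the patterns coincide);
    one distinct catalyst per reaction -> multi_enz; anything else -> other.
    """
    per_rxn = [r.catalysts for r in reactions]
    all_cats: set[str] = set().union(*per_rxn) if per_rxn else set()
    roles = {sid: ("enzyme" if sid in all_cats else "substrate") for sid in species_ids}

    if not reactions or any(len(c) != 1 for c in per_rxn):
        return roles, "other"
    cats = [next(iter(c)) for c in per_rxn]
    if len(set(cats)) == 1 and len(reactions) >= 2:
        return roles, "single_enz"
    if len(set(cats)) == len(reactions):
        return roles, "multi_enz"
    return roles, "other"


def read_sbml(path: str | os.PathLike) -> CRNModel:
    """Parse a document written by :func:`write_sbml` back into a CRNModel."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SBMLParseError(f"{path}: malformed XML: {exc}") from exc

    root = tree.getroot()
    if root.tag != _S + "sbml":
        raise SBMLParseError(f"{path}: root element {root.tag!r} is not SBML L3V1")
    mdl = root.find(_S + "model")
    if mdl is None:
        raise SBMLParseError(f"{path}: no <model> element")

    raw_species: list[tuple[str, float]] = []
    for sp in mdl.findall(f"{_S}listOfSpecies/{_S}species"):
        sid = sp.get("id")
        amount = sp.get("initialAmount")
        if sid is None or amount is None:
            raise SBMLParseError(f"{path}: <species> missing id or initialAmount")
        raw_species.append((sid, float(amount)))

    reactions: list[Reaction] = []
    for r_el in mdl.findall(f"{_S}listOfReactions/{_S}reaction"):
        rid = r_el.get("id") or f"R{len(reactions) + 1}"
        sides = []
        for tag in ("listOfReactants", "listOfProducts"):
            pairs = []
            for ref in r_el.findall(f"{_S}{tag}/{_S}speciesReference"):
                sid = ref.get("species")
                if sid is None:
                    raise SBMLParseError(
                        f"{path}: reaction {rid!r}: speciesReference without species"
                    )
                pairs.append((sid, int(float(ref.get("stoichiometry", "1")))))
            sides.append(tuple(pairs))
        kl = r_el.find(_S + "kineticLaw")
        if kl is None:
            raise SBMLParseError(f"{path}: reaction {rid!r} has no kineticLaw")
        k_el = kl.find(f"{_S}listOfLocalParameters/{_S}localParameter[@id='k']")
        if k_el is None:
            # L3 also allows the un-prefixed name listOfLocalParameters only;
            # anything else is outside the supported mass-action subset
            raise SBMLParseError(
                f"{path}: reaction {rid!r}: kineticLaw has no local parameter 'k' "
                "(only mass-action laws of the form k*reactants are supported)"
            )
        reactions.append(
            Reaction(id=rid, reactants=sides[0], products=sides[1], k=float(k_el.get("value")))
        )

    roles, topology = _infer_roles_and_topology([s for s, _ in raw_species], reactions)
    species = [
        Species(sid, int(round(amount)), roles[sid]) for sid, amount in raw_species
    ]
    name = mdl.get("id") or path.stem
    return CRNModel(species=species, reactions=reactions, topology=topology, name=name)  # type: ignore[arg-type]
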