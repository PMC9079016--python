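"""Read and write belief networks in the XMLBIF interchange format.

XMLBIF (XML Bayesian network Interchange Format, version 0.3) is the de-facto
text format for discrete networks.  Table entries are written with full float
repr so that a write/read round trip reproduces every probability exactly.

Table layout: one row per parent-state combination, mixed radix over the
``<GIVEN>`` parents in order (first parent most significant), with the child
state varying fastest within a row — the same layout as :class:`nadopt.bn.CPT`.
Variable roles are carried in a ``<PROPERTY>`` element.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .bn import CPT, BeliefNetwork, NetworkError, NetworkStructure, Variable

__all__ = ["write_xmlbif", "read_xmlbif"]


def write_xmlbif(net: BeliefNetwork, path: str | Path, name: str = "network") -> None:
    root = ET.Element("BIF", VERSION="0.3")
    nw = ET.SubElement(root, "NETWORK")
    ET.SubElement(nw, "NAME").text = name
    for var in net.structure.variables.values():
        ve = ET.SubElement(nw, "VARIABLE", TYPE="nature")
        ET.SubElement(ve, "NAME").text = var.name
        for s in var.states:
            ET.SubElement(ve, "OUTCOME").text = s
        ET.SubElement(ve, "PROPERTY").text = f"role = {var.role}"
    for child in net.structure.names:
        cpt = net.cpts[child]
        de = ET.SubElement(nw, "DEFINITION")
        ET.SubElement(de, "FOR").text = child
        for p in cpt.parent_names:
            ET.SubElement(de, "GIVEN").text = p
        ET.SubElement(de, "TABLE").text = " ".join(repr(float(x)) for x in cpt.table.ravel())
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_xmlbif(path: str | Path) -> BeliefNetwork:
    tree = ET.parse(path)
    nw = tree.getroot().find("NETWORK")
    if nw is None:
        raise NetworkError(f"{path}: no <NETWORK> element")
    variables: dict[str, Variable] = {}
    for ve in nw.findall("VARIABLE"):
        vname = ve.findtext("NAME")
        states = tuple(o.text for o in ve.findall("OUTCOME"))
        role = "predictor"
        for pe in ve.findall("PROPERTY"):
            text = (pe.text or "").strip()
            if text.startswith("role"):
                role = text.split("=", 1)[1].strip()
        variables[vname] = Variable(vname, states, role)
    edges: list[tuple[str, str]] = []
    defs: list[tuple[str, list[str], np.ndarray]] = []
    for de in nw.findall("DEFINITION"):
        child = de.findtext("FOR")
        givens = [g.text for g in de.findall("GIVEN")]
        table = np.array([float(x) for x in de.findtext("TABLE").split()])
        defs.append((child, givens, table))
        edges.extend((g, child) for g in givens)
    structure = NetworkStructure(variables.values(), edges)
    cpts = {}
    for child, givens, flat in defs:
        parents = [variables[g] for g in givens]
        n_rows = int(np.prod([p.n_states for p in parents])) if parents else 1
        cpts[child] = CPT(variables[child], parents,
                          flat.reshape(n_rows, variables[child].n_states))
    return BeliefNetwork(structure, cpts)
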