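"""Standard 10-20 scalp montage: labels, spatial adjacency, lobe/hemisphere roll-ups.

The 19-electrode 10-20 layout is the reference montage for scalp EEG seizure
work.  Spatial adjacency (used as the electrode gene's neighbourhood graph)
connects electrodes that are physically next to each other on the scalp grid:

          Fp1   Fp2
     F7   F3   Fz   F4   F8
     T3   C3   Cz   C4   T4
     T5   P3   Pz   P4   T6
          O1    O2
"""

from __future__ import annotations

import networkx as nx

#: Canonical ordering of the 19 scalp electrodes (row-major over the grid above).
ELECTRODES_10_20: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Scalp adjacency: horizontal neighbours within each row plus vertical
# neighbours between rows; the prefrontal and occipital pairs attach to the
# nearest lateral/para-sagittal positions.
ADJACENCY_10_20: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F7", "F3"),
    "Fp2": ("Fp1", "F4", "F8"),
    "F7": ("Fp1", "F3", "T3"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("F3", "F4", "Cz"),
    "F4": ("Fp2", "Fz", "F8", "C4"),
    "F8": ("Fp2", "F4", "T4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "Cz", "T4", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4"),
    "P4": ("C4", "Pz", "T6", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "O2"),
    "O2": ("T6", "P4", "O1"),
}

#: Editable electrode -> lobe assignment (Fp and F both count as frontal).
LOBE_OF: dict[str, str] = {
    "Fp1": "frontal", "Fp2": "frontal",
    "F7": "frontal", "F3": "frontal", "Fz": "frontal",
    "F4": "frontal", "F8": "frontal",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
    "C3": "central", "Cz": "central", "C4": "central",
    "P3": "parietal", "Pz": "parietal", "P4": "parietal",
    "O1": "occipital", "O2": "occipital",
}


def hemisphere_of(label: str) -> str:
    """Hemisphere from the 10-20 label: odd index = left, even = right, z = midline."""
    tail = label[-1]
    if tail in ("z", "Z"):
        return "midline"
    return "left" if int(tail) % 2 == 1 else "right"


def adjacency_graph() -> nx.Graph:
    """The 10-20 spatial adjacency as an undirected :class:`networkx.Graph`."""
    g = nx.Graph()
    g.add_nodes_from(ELECTRODES_10_20)
    for node, neighbours in ADJACENCY_10_20.items():
        for other in neighbours:
            g.add_edge(node, other)
    return g
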