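"""Marker panel and phenotype label vocabulary.

The panel mirrors a 13-channel imaging-mass-cytometry design for salivary
gland carcinoma: one epithelial marker (cytokeratin AE1/3), vascular markers
(CD31, CD34), pan-mesenchymal and CAF markers (Vimentin, aSMA, Collagen1,
CD74, Ki67), immune lineage markers (CD45, CD4, CD8a, CD138), plus a nuclear
(DNA intercalator) channel used only for segmentation QC upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical marker order for cell tables and simulators.
MARKERS = (
    "CKAE13",
    "CD31",
    "Vimentin",
    "aSMA",
    "Collagen1",
    "Ki67",
    "CD34",
    "CD74",
    "CD45",
    "CD4",
    "CD8a",
    "CD138",
    "DNA",
)

#: Level-1 compartments assigned after the tumor gate.
LEVEL1_LABELS = ("tumor", "endothelia", "immune", "CAF")

#: Final phenotype vocabulary (one label per cell).
FINAL_LABELS = (
    "tumor",
    "endothelia",
    "plasma cell",
    "CD8 T",
    "CD4 T",
    "proliferating CD4 T",
    "CD4+CD74+ T",
    "other CD4+",
    "other immune",
    "mCAF",
    "Collagen CAF",
    "SMA CAF",
    "dCAF",
    "apCAF",
    "other CAF (Vimentin+)",
)

#: Final label -> level-1 compartment.
LEVEL1_OF_FINAL = {
    "tumor": "tumor",
    "endothelia": "endothelia",
    "plasma cell": "immune",
    "CD8 T": "immune",
    "CD4 T": "immune",
    "proliferating CD4 T": "immune",
    "CD4+CD74+ T": "immune",
    "other CD4+": "immune",
    "other immune": "immune",
    "mCAF": "CAF",
    "Collagen CAF": "CAF",
    "SMA CAF": "CAF",
    "dCAF": "CAF",
    "apCAF": "CAF",
    "other CAF (Vimentin+)": "CAF",
}

ROLE_TAGS = {
    "CKAE13": "epithelial",
    "CD31": "vascular",
    "CD34": "vascular",
    "Vimentin": "CAF",
    "aSMA": "CAF",
    "Collagen1": "CAF",
    "CD74": "CAF",
    "Ki67": "proliferation",
    "CD45": "immune",
    "CD4": "immune",
    "CD8a": "immune",
    "CD138": "immune",
    "DNA": "nuclear",
}


@dataclass(frozen=True)
class MarkerPanel:
    """Named marker panel with role tags.

    Gating and clustering operations validate their marker arguments against
    ``markers`` so misspelled channels fail loudly.
    """

    markers: tuple[str, ...] = MARKERS
    roles: dict = field(default_factory=lambda: dict(ROLE_TAGS))

    def __post_init__(self):
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")

    def validate(self, names) -> None:
        unknown = [m for m in names if m not in self.markers]
        if unknown:
            raise KeyError(f"markers not in panel: {unknown}")


DEFAULT_PANEL = MarkerPanel()
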