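"""Tissue-category vocabulary.

Eight fixed categories, indexed 0..7. The pipeline only needs stable indices
plus named roles for the structurally meaningful classes (tumor, necrosis,
fibrosis); the remaining names follow common liver-histology usage. The
vocabulary is configurable wherever a :class:`TissueLabelGrid` is constructed,
with this tuple as the default.
"""

TISSUE_CATEGORIES: tuple[str, ...] = (
    "tumor",
    "necrosis",
    "fibrosis",
    "lymphocyte",
    "normal",
    "hemorrhage",
    "debris",
    "background",
)

TUMOR, NECROSIS, FIBROSIS, LYMPHOCYTE, NORMAL, HEMORRHAGE, DEBRIS, BACKGROUND = range(8)

N_CATEGORIES: int = 8
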