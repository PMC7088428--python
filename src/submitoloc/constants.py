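"""Shared constants: the residue alphabet and the four location classes."""

# Fixed alphabetical one-letter ordering used for every composition block.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# The four sub-mitochondrial compartments, in canonical order.
CLASSES = ("inner_membrane", "intermembrane_space", "matrix", "outer_membrane")

# Annotation keywords signalling each compartment, used by the
# multiple-location curation filter (case-insensitive substring match).
CLASS_KEYWORDS = {
    "inner_membrane": ("inner membrane", "inner_membrane"),
    "intermembrane_space": (
        "intermembrane space",
        "inter membrane space",
        "intermembrane_space",
    ),
    "matrix": ("matrix",),
    "outer_membrane": ("outer membrane", "outer_membrane"),
}
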