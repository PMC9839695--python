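"""Tiny element table for the alternative node-feature scheme."""

_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17,
    "K": 19, "Ca": 20, "Fe": 26, "Zn": 30, "Br": 35, "I": 53,
}


def atomic_number(element: str) -> int:
    try:
        return _Z[element.capitalize() if len(element) > 1 else element.upper()]
    except KeyError:
        raise KeyError(f"element {element!r} not in the built-in table") from None
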