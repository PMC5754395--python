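"""Muscle naming conventions, channel orders, and the instruction tables.

The perioral region is described by two muscle sets:

* the seven muscles that can be measured bilaterally with surface
  electrodes (bipolar derivations): orbicularis oris superior (OOS) and
  inferior (OOI), risorius (RIS), zygomaticus major (ZYG), levator labii
  superioris alaeque nasi (LLSAN), depressor anguli oris (DAO) and
  mentalis (MEN);
* the ten muscle groups of the biomechanical face model: orbicularis oris
  peripheralis (OOP) and marginalis (OOM), buccinator (BUC), levator
  anguli oris (LAO), depressor labii inferior (DLI), plus MEN, ZYG, RIS,
  DAO and LLSAN which exist in both sets.

Channels are always ordered left side first (indices 0..n-1) then right
side (n..2n-1), matching the bilateral-averaging convention
``mean_m = (ch[m] + ch[m+n]) / 2``.
"""

from __future__ import annotations

# Canonical muscle orders.  MODEL_MUSCLES doubles as the tie-break order
# for top-variance selection.
MEASURED_MUSCLES: tuple[str, ...] = (
    "OOS", "OOI", "RIS", "ZYG", "LLSAN", "DAO", "MEN",
)
MODEL_MUSCLES: tuple[str, ...] = (
    "OOP", "OOM", "BUC", "LAO", "DLI", "MEN", "ZYG", "RIS", "DAO", "LLSAN",
)

SIDES: tuple[str, str] = ("L", "R")

INSTRUCTIONS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")

INSTRUCTION_NAMES: dict[str, str] = {
    "A": "purse lips",
    "B": "raise upper lip",
    "C": "depress mouth corners",
    "D": "voluntary smile",
    "E": "left-right-left with closed mouth",
    "F": "purse lips - closed mouth smile - purse lips",
}

#: Relevant model muscles per instruction (the act_rel strategy table).
RELEVANT_MUSCLES: dict[str, tuple[str, ...]] = {
    "A": ("OOP", "OOM", "BUC"),
    "B": ("LLSAN",),
    "C": ("DAO", "MEN"),
    "D": ("LLSAN", "RIS", "ZYG", "LAO", "DAO", "DLI"),
    "E": ("OOP", "OOM", "LLSAN", "RIS", "ZYG", "LAO", "BUC"),
    "F": ("OOP", "OOM", "LLSAN", "RIS", "ZYG", "LAO", "BUC"),
}

#: Bipolar electrode pairs per measured muscle (left pair, right pair),
#: kept for documentation / manifest purposes.
ELECTRODES: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "OOS": ((1, 2), (15, 16)),
    "OOI": ((3, 4), (17, 18)),
    "LLSAN": ((5, 6), (19, 20)),
    "DAO": ((7, 8), (21, 22)),
    "RIS": ((9, 10), (23, 24)),
    "ZYG": ((11, 12), (25, 26)),
    "MEN": ((13, 14), (27, 28)),
}

#: Anatomically adjacent measured-channel pairs (same side) used by the
#: default cross-talk model: electrode sites that sit next to each other
#: on the skin and therefore leak signal into one another.
ADJACENT_PAIRS: tuple[tuple[str, str], ...] = (
    ("OOS", "OOI"),
    ("OOS", "LLSAN"),
    ("OOI", "MEN"),
    ("OOI", "DAO"),
    ("RIS", "ZYG"),
    ("DAO", "MEN"),
)


def measured_labels() -> list[str]:
    """14 measured channel labels, left block then right block."""
    return [f"{m}_{s}" for s in SIDES for m in MEASURED_MUSCLES]


def model_labels() -> list[str]:
    """20 model channel labels, left block then right block."""
    return [f"{m}_{s}" for s in SIDES for m in MODEL_MUSCLES]


def channel_index(labels: list[str] | tuple[str, ...], label: str) -> int:
    try:
        return list(labels).index(label)
    except ValueError as exc:
        raise KeyError(f"unknown channel label {label!r}") from exc


def check_instruction(instruction: str) -> str:
    """Validate an instruction id, returning it unchanged."""
    if instruction not in INSTRUCTIONS:
        known = ", ".join(
            f"{k} ({INSTRUCTION_NAMES[k]})" for k in INSTRUCTIONS
        )
        raise ValueError(
            f"unknown instruction {instruction!r}; expected one of: {known}"
        )
    return instruction
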