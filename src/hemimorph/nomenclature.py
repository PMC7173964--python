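"""Neuron-type nomenclature.

A type name is ``<lineage><A|B?>_<class letter><2-digit serial>(<annotation>)``,
e.g. ``ALv1_P07``, ``AOTUv4B_H05``, ``SMPp&v1B_T01(VESc)``.  The optional A/B
suffix marks the Notch-on (A) or Notch-off (B) hemilineage of a dual lineage;
lone hemilineages carry no suffix.  The class letter encodes neuron topology:
S (Single), P (Projection), C (Central), M (Midline), T (Transverse),
H (Horizontal) and D (External, e.g. descending neurons).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = ["TypeName", "TypeNameError", "parse_type_name", "hemilineage_key"]

CLASS_LETTERS = "SPCMTHD"

_TAIL_RE = re.compile(
    r"^(?P<cls>[A-Z])(?P<serial>[0-9]+)(?:\((?P<ann>.*)\))?$"
)


class TypeNameError(ValueError):
    pass


@dataclass(frozen=True)
class TypeName:
    lineage: str
    notch_suffix: Optional[str]  # "A" | "B" | None (lone hemilineage)
    class_letter: str
    serial: int
    annotation: Optional[str] = None

    @property
    def hemilineage(self) -> str:
        """Hemilineage key: lineage plus A/B suffix, bare lineage when lone."""
        return self.lineage + (self.notch_suffix or "")

    def render(self) -> str:
        ann = f"({self.annotation})" if self.annotation is not None else ""
        return f"{self.hemilineage}_{self.class_letter}{self.serial:02d}{ann}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_type_name(name: str) -> TypeName:
    """Parse a rendered type name; ``parse o render`` is the identity.

    Raises :class:`TypeNameError` naming the offending token on names with
    no underscore, an unknown class letter, or a non-numeric serial.
    """
    if not name:
        raise TypeNameError("empty type name")
    if "_" not in name:
        raise TypeNameError(f"{name!r}: no underscore separating lineage and class")
    stem, tail = name.rsplit("_", 1)
    if not stem:
        raise TypeNameError(f"{name!r}: empty lineage part")
    m = _TAIL_RE.match(tail)
    if m is None:
        raise TypeNameError(f"{name!r}: cannot parse class/serial token {tail!r}")
    cls = m.group("cls")
    if cls not in CLASS_LETTERS:
        raise TypeNameError(f"{name!r}: unknown topology class letter {cls!r}")
    serial = int(m.group("serial"))
    suffix: Optional[str] = None
    lineage = stem
    # dual-hemilineage names end in A or B; lineage names themselves end in a digit
    if len(stem) > 1 and stem[-1] in "AB" and not stem[:-1][-1].isalpha():
        suffix = stem[-1]
        lineage = stem[:-1]
    return TypeName(
        lineage=lineage,
        notch_suffix=suffix,
        class_letter=cls,
        serial=serial,
        annotation=m.group("ann"),
    )


def hemilineage_key(name: str) -> str:
    """Hemilineage key of a rendered type name (lineage + optional A/B)."""
    return parse_type_name(name).hemilineage
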