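"""Sample identity codes and label parsing for the adulteration study design.

The study comprises 2 honeys (MAN: Manuka, JAR: Jarrah), 6 sugar syrups
(RIC: rice, COR: corn, GOL: golden, TRE: treacle, GLU: glucose, MAP: maple)
and every honey x syrup blend at 10-50 % (w/w) in 10 % steps, i.e.
2 + 6 + 2*6*5 = 68 distinct samples.

Labels are written ``MAN`` for pure products and ``MAN-RIC 10%`` for blends;
the parser also tolerates ``_`` and extra whitespace as separators and a
missing ``%`` sign.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

HONEYS: tuple[str, ...] = ("MAN", "JAR")
SYRUPS: tuple[str, ...] = ("RIC", "COR", "GOL", "TRE", "GLU", "MAP")
PRODUCTS: tuple[str, ...] = HONEYS + SYRUPS
BLEND_LEVELS: tuple[int, ...] = (10, 20, 30, 40, 50)

_LABEL_RE = re.compile(
    r"^\s*(?P<base>[A-Za-z]{3})"
    r"(?:[-_\s]+(?P<adulterant>[A-Za-z]{3})[-_\s]*(?P<level>\d+)\s*%?)?\s*$"
)


class LabelError(ValueError):
    """Raised for malformed or design-violating sample labels."""


@dataclass(frozen=True, order=True)
class SampleLabel:
    """Identity of one sample: a pure product or a honey/syrup blend.

    ``level`` is the adulterant mass fraction in percent w/w; it is 0 if and
    only if the sample is a pure product (``adulterant is None``).
    """

    base: str
    adulterant: str | None = None
    level: int = 0

    def __post_init__(self) -> None:
        if self.base not in PRODUCTS:
            raise LabelError(f"unknown product code {self.base!r}")
        if self.adulterant is None:
            if self.level != 0:
                raise LabelError("pure product must have level 0")
        else:
            if self.base not in HONEYS:
                raise LabelError(
                    f"adulterant on a syrup base {self.base!r} is not part of the design"
                )
            if self.adulterant not in SYRUPS:
                raise LabelError(f"unknown adulterant code {self.adulterant!r}")
            if not 0 < self.level < 100:
                raise LabelError(f"blend level must be in (0, 100), got {self.level}")

    @property
    def is_blend(self) -> bool:
        return self.adulterant is not None

    def __str__(self) -> str:
        return format_sample_label(self)


def format_sample_label(label: SampleLabel) -> str:
    """Canonical text form: ``MAN`` or ``MAN-RIC 10%``."""
    if label.adulterant is None:
        return label.base
    return f"{label.base}-{label.adulterant} {label.level}%"


def parse_sample_label(text: str) -> SampleLabel:
    """Parse ``<BASE>`` or ``<BASE>-<ADULTERANT> <LEVEL>%`` into a SampleLabel.

    Separators may be hyphens, underscores or spaces; the percent sign is
    optional. Raises :class:`LabelError` on unknown codes, a level outside
    the design, or an adulterant attached to a syrup base.
    """
    m = _LABEL_RE.match(text)
    if m is None:
        raise LabelError(f"cannot parse sample label {text!r}")
    base = m.group("base").upper()
    adulterant = m.group("adulterant")
    if adulterant is None:
        return SampleLabel(base)
    level = int(m.group("level"))
    if level not in BLEND_LEVELS:
        raise LabelError(f"blend level must be one of {BLEND_LEVELS}, got {level}")
    return SampleLabel(base, adulterant.upper(), level)


def design_labels(
    honeys: tuple[str, ...] = HONEYS,
    syrups: tuple[str, ...] = SYRUPS,
    levels: tuple[int, ...] = BLEND_LEVELS,
) -> list[SampleLabel]:
    """All labels of the full design in canonical order.

    Pure honeys, then pure syrups, then blends grouped by honey, syrup and
    ascending level. The default design yields exactly 68 labels.
    """
    labels = [SampleLabel(h) for h in honeys]
    labels += [SampleLabel(s) for s in syrups]
    for h in honeys:
        for s in syrups:
            for lv in levels:
                labels.append(SampleLabel(h, s, lv))
    return labels
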