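"""Synthetic honey/syrup/blend profile generator.

Emulates the compositional structure of the 68-sample adulteration study:
two honeys with rich organic fingerprints and fructose/glucose-dominated
sugar profiles, three maltose-rich starch syrups (rice, corn, glucose),
three sucrose-rich syrups (golden, treacle, maple; maple carrying its
signifying organic marker band at Rf 0.41), and all 60 blends at
10-50 % (w/w).

Blending is linear in mass fraction for both sugars and band intensities,
so increasing the adulterant fraction dilutes the honey bands
proportionally while the adulterant's sugars (maltose or sucrose) rise.
Per-sample measurement noise is multiplicative truncated-Gaussian with a
per-quantity coefficient of variation; band positions are never jittered
here (run-to-run Rf drift is the augmentation module's job), so generator
output stays grid-alignable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .labels import BLEND_LEVELS, HONEYS, SYRUPS, SampleLabel
from .profiles import CHANNELS, SUGARS, ProfileTable, SampleRecord, records_to_table


@dataclass(frozen=True)
class ProductTemplate:
    """Ground-truth composition of one pure product.

    ``sugar_means`` are in quantification units on the study's 0 to ~2,000
    dynamic range; ``bands`` are (channel, Rf centre, mean AU) with AU in
    [0, 1]; ``sugar_cvs`` / ``band_cv`` are relative measurement dispersions.
    """

    code: str
    sugar_means: dict[str, float]
    bands: tuple[tuple[str, float, float], ...]
    sugar_cvs: dict[str, float] = field(default_factory=dict)
    band_cv: float = 0.05

    def __post_init__(self) -> None:
        for s in SUGARS:
            if self.sugar_means.get(s, 0.0) < 0:
                raise ValueError(f"{self.code}: negative {s} mean")
        for channel, rf, au in self.bands:
            if channel not in CHANNELS:
                raise ValueError(f"{self.code}: unknown channel {channel!r}")
            if not 0.0 < rf < 1.0:
                raise ValueError(f"{self.code}: Rf centre {rf} outside (0, 1)")
            if not 0.0 <= au <= 1.0:
                raise ValueError(f"{self.code}: mean AU {au} outside [0, 1]")

    def cv_for(self, sugar: str) -> float:
        return self.sugar_cvs.get(sugar, 0.05)

    def record(self) -> SampleRecord:
        """Noiseless pure-product record at the template means."""
        return SampleRecord(
            SampleLabel(self.code),
            {s: float(self.sugar_means.get(s, 0.0)) for s in SUGARS},
            {(ch, rf): au for ch, rf, au in self.bands if au > 0},
        )


def _sug(fructose: float, glucose: float, maltose: float, sucrose: float) -> dict[str, float]:
    return {
        "fructose": fructose,
        "glucose": glucose,
        "maltose": maltose,
        "sucrose": sucrose,
    }


def default_templates() -> list[ProductTemplate]:
    """The eight study products.

    Honeys: fructose/glucose dominant, trace maltose, no quantifiable
    sucrose; Manuka and Jarrah differ in their fructose/glucose ratio
    (Jarrah is the classic high-fructose honey) and in their organic band
    positions. Starch syrups (RIC/COR/GLU) are maltose-rich with mutually
    similar sugar spectra; cane/maple syrups (GOL/TRE/MAP) are
    sucrose-rich. Syrup extracts carry no major organic bands, only a pair
    of minor derivatisation-visualised bands each, except maple's strong
    marker at Rf 0.41.
    """
    return [
        ProductTemplate(
            "MAN",
            _sug(950, 800, 30, 0),
            (
                ("R254", 0.12, 0.80),
                ("R254", 0.27, 0.55),
                ("R254", 0.46, 0.70),
                ("R366", 0.09, 0.65),
                ("R366", 0.33, 0.90),
                ("R366", 0.52, 0.45),
                ("R366_D", 0.17, 0.75),
                ("R366_D", 0.30, 0.60),
                ("R366_D", 0.49, 0.85),
                ("R366_D", 0.57, 0.40),
                ("TW_D", 0.225, 0.30),
            ),
        ),
        ProductTemplate(
            "JAR",
            _sug(1150, 550, 25, 0),
            (
                ("R254", 0.15, 0.70),
                ("R254", 0.36, 0.85),
                ("R254", 0.55, 0.50),
                ("R366", 0.20, 0.75),
                ("R366", 0.40, 0.60),
                ("R366", 0.58, 0.80),
                ("R366_D", 0.11, 0.55),
                ("R366_D", 0.25, 0.90),
                ("R366_D", 0.36, 0.65),
                ("R366_D", 0.53, 0.35),
                ("TW_D", 0.35, 0.28),
            ),
        ),
        ProductTemplate(
            "RIC",
            _sug(30, 200, 700, 0),
            (("TW_D", 0.06, 0.40), ("TW_D", 0.43, 0.30)),
        ),
        ProductTemplate(
            "COR",
            _sug(80, 300, 620, 0),
            (("TW_D", 0.10, 0.35), ("TW_D", 0.47, 0.32)),
        ),
        ProductTemplate(
            "GOL",
            _sug(370, 310, 0, 720),
            (("TW_D", 0.14, 0.38), ("TW_D", 0.51, 0.30)),
        ),
        ProductTemplate(
            "TRE",
            _sug(220, 180, 0, 950),
            (("TW_D", 0.18, 0.42), ("TW_D", 0.55, 0.35)),
        ),
        ProductTemplate(
            "GLU",
            _sug(20, 420, 540, 0),
            (("TW_D", 0.265, 0.33), ("TW_D", 0.39, 0.30)),
        ),
        ProductTemplate(
            "MAP",
            _sug(40, 30, 0, 830),
            (
                ("R366_D", 0.41, 0.85),  # maple's signifying marker band
                ("TW_D", 0.305, 0.30),
                ("TW_D", 0.59, 0.28),
            ),
        ),
    ]


@dataclass(frozen=True)
class StudyDesignConfig:
    """Design and noise model of one synthetic study.

    ``noise_scale`` multiplies every template CV; 0 gives the exact linear
    mixing rule. The default design is 2 honeys + 6 syrups + 60 blends = 68.
    """

    templates: tuple[ProductTemplate, ...] = tuple(default_templates())
    honeys: tuple[str, ...] = HONEYS
    syrups: tuple[str, ...] = SYRUPS
    levels: tuple[int, ...] = BLEND_LEVELS
    noise_scale: float = 1.0
    seed: int = 0

    def template_map(self) -> dict[str, ProductTemplate]:
        codes = [t.code for t in self.templates]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate product codes in templates")
        return {t.code: t for t in self.templates}


def blend(honey: SampleRecord, syrup: SampleRecord, fraction: float) -> SampleRecord:
    """Mix a honey and a syrup record at the given adulterant mass fraction.

    Sugars and band intensities combine linearly over the union of band
    positions: value = (1 - fraction) * honey + fraction * syrup. The label
    becomes (honey base, syrup base, 100 * fraction).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if honey.label.base not in HONEYS or honey.label.is_blend:
        raise ValueError("first argument must be a pure honey")
    if syrup.label.base not in SYRUPS or syrup.label.is_blend:
        raise ValueError("second argument must be a pure syrup")
    if fraction == 0.0:
        return SampleRecord(honey.label, dict(honey.sugars), dict(honey.bands))
    if fraction == 1.0:
        return SampleRecord(syrup.label, dict(syrup.sugars), dict(syrup.bands))
    sugars = {
        s: (1.0 - fraction) * honey.sugars[s] + fraction * syrup.sugars[s]
        for s in SUGARS
    }
    bands: dict[tuple[str, float], float] = {}
    for pos in set(honey.bands) | set(syrup.bands):
        bands[pos] = (1.0 - fraction) * honey.bands.get(pos, 0.0) + fraction * syrup.bands.get(pos, 0.0)
    level = int(round(100 * fraction))
    return SampleRecord(SampleLabel(honey.label.base, syrup.label.base, level), sugars, bands)


def _apply_noise(
    record: SampleRecord, template_cvs, band_cv: float, scale: float, rng: np.random.Generator
) -> SampleRecord:
    """Multiplicative truncated-Gaussian measurement noise on one sample."""
    sugars = {}
    for s in SUGARS:
        cv = scale * template_cvs(s)
        sugars[s] = record.sugars[s] * max(0.0, 1.0 + cv * rng.standard_normal())
    bands = {}
    for pos, au in record.bands.items():
        noisy = au * max(0.0, 1.0 + scale * band_cv * rng.standard_normal())
        bands[pos] = min(1.0, noisy)
    return SampleRecord(record.label, sugars, bands)


def generate_study(config: StudyDesignConfig) -> ProfileTable:
    """Generate the full study table: pure products then all blends.

    Noiseless profiles follow the linear mixing rule exactly; measurement
    noise is then applied independently per sample. Deterministic under the
    config seed.
    """
    tmpl = config.template_map()
    for code in tuple(config.honeys) + tuple(config.syrups):
        if code not in tmpl:
            raise ValueError(f"no template for product {code!r}")
    rng = np.random.default_rng(config.seed)
    pure = {code: tmpl[code].record() for code in tmpl}

    ordered: list[tuple[SampleRecord, ProductTemplate]] = []
    for h in config.honeys:
        ordered.append((pure[h], tmpl[h]))
    for s in config.syrups:
        ordered.append((pure[s], tmpl[s]))
    for h in config.honeys:
        for s in config.syrups:
            for lv in config.levels:
                rec = blend(pure[h], pure[s], lv / 100.0)
                # blend-level dispersion: adulterant-fraction-weighted mix of
                # the parents' CVs
                f = lv / 100.0
                cvs = {
                    sg: (1 - f) * tmpl[h].cv_for(sg) + f * tmpl[s].cv_for(sg)
                    for sg in SUGARS
                }
                band_cv = (1 - f) * tmpl[h].band_cv + f * tmpl[s].band_cv
                ordered.append((rec, replace(tmpl[h], sugar_cvs=cvs, band_cv=band_cv)))

    noisy = [
        _apply_noise(rec, t.cv_for, t.band_cv, config.noise_scale, rng)
        for rec, t in ordered
    ]
    return records_to_table(noisy, provenance=f"synthetic(seed={config.seed})")
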