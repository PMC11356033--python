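"""Synthetic annotation tables with known retention structure.

The generator emulates what the retention model assumes about a real
reversed-phase lipidomics run: retention time has linear latent
structure in acyl chain length (H count), saturation (double-bond
equivalents, visible through the C-H relationship) and a class-specific
headgroup offset, plus Gaussian noise:

    tR = offset(class) + coef_H * H + coef_unsat * DBE + N(0, noise_sd)

Formulas are built from per-class homologous-series templates
(H = 2C + h_offset − 2·DBE with fixed heteroatoms), so the latent
variables are exactly recoverable from element counts and class — a
clean testbed for the QC pipeline. Misannotations are injected by
swapping the class label or perturbing the H count while leaving the
observed retention time at the true lipid's value; the induced shift
(generating-model tR of the recorded identity minus the true identity)
is recorded so detection tests can condition on detectability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import MS1, MS2, AnnotationTable, LipidAnnotation
from .formula import parse_formula, to_hill

__all__ = [
    "ClassSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_lipidome",
    "inject_misannotations",
    "simulate",
]


@dataclass(frozen=True)
class ClassSpec:
    """Homologous-series template for one lipid class.

    ``h_offset`` closes the formula: H = 2*C + h_offset − 2*DBE.
    ``extra`` lists the fixed heteroatoms of the headgroup/backbone.
    ``offset_min`` is the class's headgroup retention offset in minutes.
    """

    name: str
    offset_min: float
    h_offset: int
    extra: dict[str, int]
    carbon_range: tuple[int, int]
    dbe_range: tuple[int, int]

    def formula(self, carbons: int, dbe: int) -> str:
        h = 2 * carbons + self.h_offset - 2 * dbe
        if h < 2:
            raise ValueError(f"{self.name}: C{carbons} DBE {dbe} gives H {h}")
        comp = {"C": carbons, "H": h, **self.extra}
        return to_hill(comp)

    def dbe_of(self, composition: dict[str, int]) -> float:
        """Invert the template: double-bond equivalents from a formula."""
        return (2 * composition["C"] + self.h_offset - composition.get("H", 0)) / 2


# Offsets and coefficients chosen to land retention times in the
# 1-12 min window typical of a 15-min reversed-phase lipidomics run.
DEFAULT_CLASSES = (
    ClassSpec("TG", 6.0, -4, {"O": 6}, (45, 57), (0, 6)),
    ClassSpec("DG", 5.0, -2, {"O": 5}, (31, 41), (0, 4)),
    ClassSpec("PC", 4.2, 0, {"N": 1, "O": 8, "P": 1}, (34, 44), (0, 6)),
    ClassSpec("Cer", 5.5, 1, {"N": 1, "O": 3}, (34, 44), (0, 3)),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for a synthetic lipidome."""

    n: int = 250
    classes: tuple[ClassSpec, ...] = DEFAULT_CLASSES
    coef_H: float = 0.03  # min per H atom (acyl length proxy)
    coef_unsat: float = -0.15  # min per double-bond equivalent
    noise_sd: float = 0.1  # min
    runtime_min: float = 15.0
    min_rt: float = 1.0
    ms2_frac: float = 0.5
    misannotation_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.misannotation_frac < 1:
            raise ValueError("misannotation_frac must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.classes:
            raise ValueError("at least one class is required")

    def class_by_name(self, name: str) -> ClassSpec:
        for spec in self.classes:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def model_rt(self, spec: ClassSpec, h: int, dbe: float) -> float:
        """Noise-free generating-model retention time, minutes."""
        return spec.offset_min + self.coef_H * h + self.coef_unsat * dbe


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated annotation table."""

    table: pd.DataFrame  # id, is_misannotated, true_class, true_formula,
    #                      misannotation_kind, induced_shift_min
    config: SyntheticConfig

    @property
    def n_misannotated(self) -> int:
        return int(self.table["is_misannotated"].sum())


def generate_lipidome(config: SyntheticConfig) -> tuple[AnnotationTable, SyntheticTruth]:
    """Draw a clean annotation table from the generating model.

    Fully reproducible from ``config.seed``; retention times are
    clipped into (min_rt, runtime_min].
    """
    rng = np.random.default_rng(config.seed)
    rows: list[LipidAnnotation] = []
    records = []
    for i in range(config.n):
        spec = config.classes[rng.integers(len(config.classes))]
        c = int(rng.integers(spec.carbon_range[0], spec.carbon_range[1] + 1))
        dbe = int(rng.integers(spec.dbe_range[0], spec.dbe_range[1] + 1))
        formula = spec.formula(c, dbe)
        comp = parse_formula(formula)
        rt = config.model_rt(spec, comp["H"], dbe) + rng.normal(0, config.noise_sd)
        rt = float(np.clip(rt, np.nextafter(config.min_rt, np.inf), config.runtime_min))
        ms_level = MS2 if rng.random() < config.ms2_frac else MS1
        acyl = c - (3 if spec.extra.get("O", 0) >= 5 else 0)
        rows.append(
            LipidAnnotation(
                id=f"synth-{i}",
                name=f"{spec.name} {acyl}:{dbe}",
                lipid_class=spec.name,
                formula=formula,
                composition=comp,
                rt_min=rt,
                ms_level=ms_level,
                platform="synthetic",
            )
        )
        records.append(
            {
                "id": f"synth-{i}",
                "is_misannotated": False,
                "true_class": spec.name,
                "true_formula": formula,
                "misannotation_kind": "",
                "induced_shift_min": 0.0,
            }
        )
    table = AnnotationTable(
        annotations=rows,
        runtime_min=config.runtime_min,
        platform="synthetic",
        source=f"synthetic(seed={config.seed})",
    )
    return table, SyntheticTruth(pd.DataFrame(records), config)


def inject_misannotations(
    table: AnnotationTable,
    truth: SyntheticTruth,
    config: SyntheticConfig | None = None,
    kinds: tuple[str, ...] = ("class_swap", "saturation"),
) -> tuple[AnnotationTable, SyntheticTruth]:
    """Corrupt labels on round(misannotation_frac * n) rows.

    ``class_swap`` relabels the lipid to another configured class;
    ``saturation`` perturbs the recorded H count by an even amount.
    The observed retention time never changes — it belongs to the true
    lipid — so the recorded identity becomes inconsistent with it by
    the recorded ``induced_shift_min``.
    """
    config = config or truth.config
    if "class_swap" in kinds and len(config.classes) < 2:
        raise ValueError("class_swap misannotations need at least 2 classes")
    n_mis = int(np.floor(config.misannotation_frac * len(table) + 0.5))
    rng = np.random.default_rng(config.seed + 2**20)
    rows = list(table.annotations)
    truth_df = truth.table.copy()
    if n_mis == 0:
        return table, SyntheticTruth(truth_df, config)
    chosen = rng.choice(len(rows), size=n_mis, replace=False)
    for idx in np.sort(chosen):
        a = rows[idx]
        spec = config.class_by_name(a.lipid_class)
        dbe_true = spec.dbe_of(a.composition)
        rt_true = config.model_rt(spec, a.composition["H"], dbe_true)
        kind = kinds[rng.integers(len(kinds))]
        if kind == "class_swap":
            # a misidentified lipid is reported with a formula matching the
            # wrong class: rebuild from the new template at the same carbon
            # count and unsaturation, keeping the observed (true) tR
            others = [s for s in config.classes if s.name != a.lipid_class]
            new_spec = others[rng.integers(len(others))]
            c = a.composition["C"]
            formula = new_spec.formula(c, int(dbe_true))
            comp = parse_formula(formula)
            rt_rec = config.model_rt(new_spec, comp["H"], dbe_true)
            acyl = c - (3 if new_spec.extra.get("O", 0) >= 5 else 0)
            new = dataclasses.replace(
                a,
                lipid_class=new_spec.name,
                formula=formula,
                composition=comp,
                name=f"{new_spec.name} {acyl}:{int(dbe_true)}",
            )
        else:  # saturation: H count off by 2k, tR left untouched
            k = int(rng.integers(4, 11)) * (1 if rng.random() < 0.5 else -1)
            comp = dict(a.composition)
            comp["H"] = comp["H"] + 2 * k
            if comp["H"] < 2:
                comp["H"] = a.composition["H"] + 2 * abs(k)
            formula = to_hill(comp)
            dbe_rec = spec.dbe_of(comp)
            rt_rec = config.model_rt(spec, comp["H"], dbe_rec)
            new = dataclasses.replace(a, formula=formula, composition=comp)
        rows[idx] = new
        sel = truth_df["id"] == a.id
        truth_df.loc[sel, "is_misannotated"] = True
        truth_df.loc[sel, "misannotation_kind"] = kind
        truth_df.loc[sel, "induced_shift_min"] = rt_rec - rt_true
    return table.replace(rows), SyntheticTruth(truth_df, config)


def simulate(config: SyntheticConfig) -> tuple[AnnotationTable, SyntheticTruth]:
    """Generate a lipidome and apply the configured misannotation rate."""
    table, truth = generate_lipidome(config)
    if config.misannotation_frac > 0:
        table, truth = inject_misannotations(table, truth, config)
    return table, truth
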