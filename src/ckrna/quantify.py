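"""Downstream quantitative readouts: mycorrhizal colonization and RT-qPCR.

Trouvelot scoring assigns every root fragment an ordinal colonization
intensity class 0-5 plus arbuscule (A0-A3) and vesicle (V0-V3) abundance
classes; the indices F% (frequency), M%/m% (intensity of the whole root system
/ of colonized fragments), a%/A% (arbuscule abundance in colonized fragments /
whole system) and v%/V% are weighted averages with the standard class weights
(intensity 1,2,3,4,5 -> 1,5,30,70,95; abundance classes 1,2,3 -> 10,50,100).

Relative expression uses the plain 2^(-ddCt) method without efficiency
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

INTENSITY_WEIGHT = {0: 0, 1: 1, 2: 5, 3: 30, 4: 70, 5: 95}
ABUNDANCE_WEIGHT = {1: 10, 2: 50, 3: 100}  # classes A1/A2/A3 and V1/V2/V3


@dataclass(frozen=True)
class FragmentScore:
    """Microscopy scores for one root fragment."""

    fragment_id: str
    intensity: int  # 0..5
    arbuscule: int  # 0..3 (class A0..A3)
    vesicle: int = 0  # 0..3 (class V0..V3)

    def __post_init__(self) -> None:
        if self.intensity not in INTENSITY_WEIGHT:
            raise ValueError(f"fragment {self.fragment_id}: intensity class {self.intensity} outside 0-5")
        for label, v in (("arbuscule", self.arbuscule), ("vesicle", self.vesicle)):
            if v not in (0, 1, 2, 3):
                raise ValueError(f"fragment {self.fragment_id}: {label} class {v} outside 0-3")
        if self.intensity == 0 and (self.arbuscule or self.vesicle):
            raise ValueError(
                f"fragment {self.fragment_id}: uncolonized fragment cannot carry arbuscule/vesicle classes"
            )


@dataclass(frozen=True)
class TrouvelotResult:
    F_pct: float
    M_pct: float
    m_pct: float
    a_pct: float
    A_pct: float
    v_pct: float
    V_pct: float
    n_fragments: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "F%": self.F_pct,
                "M%": self.M_pct,
                "m%": self.m_pct,
                "a%": self.a_pct,
                "A%": self.A_pct,
                "v%": self.v_pct,
                "V%": self.V_pct,
                "n": self.n_fragments,
            }
        )


def _abundance_indices(fragments: Sequence[FragmentScore], which: str, N: int, M: float) -> tuple[float, float]:
    """(x%, X%) for arbuscules (which='arbuscule') or vesicles ('vesicle')."""
    if M == 0:
        if any(getattr(f, which) for f in fragments):
            raise ValueError(f"M%=0 but nonzero {which} classes present")
        return 0.0, 0.0
    m_cls = {}
    for cls in (1, 2, 3):
        weighted = sum(INTENSITY_WEIGHT[f.intensity] for f in fragments if getattr(f, which) == cls)
        m_cls[cls] = weighted / N * 100.0 / M
    x = sum(ABUNDANCE_WEIGHT[cls] * m_cls[cls] for cls in (1, 2, 3)) / 100.0
    X = x * M / 100.0
    return x, X


def trouvelot_indices(fragments: Iterable[FragmentScore]) -> TrouvelotResult:
    """Colonization indices from per-fragment ordinal scores.

    F% = colonized fragments / N x 100; M% is the intensity-weighted average
    over all fragments; m% rescales M% to colonized fragments only; a%/A% and
    v%/V% weight the intensity of fragments carrying each abundance class.
    Invariant under fragment reordering and under duplicating the whole table.
    """
    fragments = list(fragments)
    N = len(fragments)
    if N == 0:
        raise ValueError("trouvelot_indices requires at least one fragment")
    colonized = sum(1 for f in fragments if f.intensity > 0)
    F = 100.0 * colonized / N
    M = sum(INTENSITY_WEIGHT[f.intensity] for f in fragments) / N
    m = M * N / colonized if colonized else 0.0
    a, A = _abundance_indices(fragments, "arbuscule", N, M)
    v, V = _abundance_indices(fragments, "vesicle", N, M)
    return TrouvelotResult(F, M, m, a, A, v, V, N)


def read_fragment_table(path) -> list[FragmentScore]:
    """TSV with columns fragment_id / intensity / arbuscule / vesicle."""
    df = pd.read_csv(path, sep="\t")
    return [
        FragmentScore(str(r.fragment_id), int(r.intensity), int(r.arbuscule), int(getattr(r, "vesicle", 0)))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# ddCt relative expression

@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    gene_id: str
    reference_gene_id: str
    ct_target: float
    ct_reference: float
    condition: str

    def __post_init__(self) -> None:
        for label, ct in (("target", self.ct_target), ("reference", self.ct_reference)):
            if not 0 < ct <= 45:
                raise ValueError(f"{self.sample_id}/{self.gene_id}: Ct_{label}={ct} outside (0, 45]")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(
    measurements: Iterable[QpcrMeasurement],
    control_condition: str,
) -> pd.Series:
    """Per-gene fold change 2^(-ddCt) of treatment relative to control.

    dCt = Ct_target - Ct_reference per sample; ddCt is the difference of the
    condition means.  Requires at least one control and one treatment
    measurement per gene; adding a constant to every Ct leaves the result
    unchanged.
    """
    rows = [
        (m.gene_id, m.condition == control_condition, m.delta_ct) for m in measurements
    ]
    if not rows:
        raise ValueError("no measurements")
    df = pd.DataFrame(rows, columns=["gene", "is_control", "dct"])
    folds = {}
    for gene, sub in df.groupby("gene"):
        ctrl = sub.loc[sub.is_control, "dct"]
        trt = sub.loc[~sub.is_control, "dct"]
        if ctrl.empty or trt.empty:
            raise ValueError(f"gene {gene!r}: need >=1 control and >=1 treatment measurement")
        ddct = trt.mean() - ctrl.mean()
        folds[gene] = 2.0 ** (-ddct)
    return pd.Series(folds).sort_index()


def read_ct_table(path) -> list[QpcrMeasurement]:
    """TSV with columns sample_id / gene_id / reference_gene_id / ct_target /
    ct_reference / condition."""
    df = pd.read_csv(path, sep="\t")
    return [
        QpcrMeasurement(
            str(r.sample_id),
            str(r.gene_id),
            str(r.reference_gene_id),
            float(r.ct_target),
            float(r.ct_reference),
            str(r.condition),
        )
        for r in df.itertuples(index=False)
    ]
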