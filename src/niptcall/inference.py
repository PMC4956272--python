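"""Fetal fraction, sex-call cutoff, classification and cohort scoring.

The fetal DNA concentration (fetal fraction) F of a male-fetus pregnancy is
estimated from chrY dosage:

    F = (%chrY_MF - %chrY_FF) / (%chrY_AM - %chrY_FF)

where %chrY_MF is the sample's chrY UMR percentage, %chrY_FF the median over
female-fetus pregnancies (background mismapping level) and %chrY_AM the
median over adult males (the 100%-male level). Inverting the formula at an
assumed minimal fetal fraction F* (default 1%) gives the sex-call cutoff

    cutoff = F* * (%chrY_AM - %chrY_FF) + %chrY_FF

A sample at or above the cutoff is called male. The same machinery applies
to original (unmasked) and optimized (chrY-masked) percentages; only the
panel medians differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class ReferencePanel:
    """chrY-percentage reference medians and the assumed minimal fetal fraction.

    ``pct_chrY_ff``: median chrY percentage of female-fetus pregnancies.
    ``pct_chrY_am``: median chrY percentage of adult males.
    ``f_assumed``:   fetal fraction at which the cutoff is placed.
    ``variant``:     which percentage the panel applies to
                     ("original" = unmasked, "masked" = six regions removed).
    """

    pct_chrY_ff: float
    pct_chrY_am: float
    f_assumed: float = 0.01
    variant: str = "original"
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pct_chrY_ff < self.pct_chrY_am <= 1:
            raise ValueError(
                f"panel requires 0 <= FF < AM <= 1, got FF={self.pct_chrY_ff}, "
                f"AM={self.pct_chrY_am}"
            )
        if not 0 < self.f_assumed <= 1:
            raise ValueError(f"f_assumed must be in (0, 1], got {self.f_assumed}")

    @property
    def cutoff_chrY_mf(self) -> float:
        return derive_cutoff(self)

    @classmethod
    def from_cohort(
        cls,
        pct_chrY_female_fetus: Sequence[float],
        pct_chrY_adult_male: Sequence[float],
        f_assumed: float = 0.01,
        variant: str = "original",
    ) -> "ReferencePanel":
        """Build a panel from cohort percentages via the median."""
        return cls(
            pct_chrY_ff=float(np.median(pct_chrY_female_fetus)),
            pct_chrY_am=float(np.median(pct_chrY_adult_male)),
            f_assumed=f_assumed,
            variant=variant,
        )


#: Published reference medians from a 92-pregnancy / 3-adult-male panel
#: (original = unmasked chrY percentage, optimized = six regions masked).
PANELS: dict[str, ReferencePanel] = {
    "paper2016-original": ReferencePanel(
        4.22e-5, 1.73e-3, f_assumed=0.01, variant="original", name="paper2016-original"
    ),
    "paper2016-optimized": ReferencePanel(
        3.02e-6, 3.74e-4, f_assumed=0.01, variant="masked", name="paper2016-optimized"
    ),
}

#: Cutoff printed alongside the optimized panel in the original publication
#: (0.00002). The formula applied to the published medians gives 6.73e-6
#: instead; the formula-derived value is what `derive_cutoff` returns, and
#: this constant is provided for users who want the published number as-is.
PUBLISHED_OPTIMIZED_CUTOFF: float = 2e-5


def estimate_fetal_fraction(pct_chrY_mf: float, panel: ReferencePanel) -> float:
    """F = (%chrY_MF - %chrY_FF) / (%chrY_AM - %chrY_FF).

    Negative values (female-fetus samples below the background median) and
    values above 1 are returned as-is for QC; >1.5 warns about a likely
    panel mis-specification.
    """
    denom = panel.pct_chrY_am - panel.pct_chrY_ff
    if denom <= 0:
        raise ValueError("degenerate panel: %chrY_AM must exceed %chrY_FF")
    f = (pct_chrY_mf - panel.pct_chrY_ff) / denom
    if f > 1.5:
        warnings.warn(
            f"fetal fraction estimate {f:.3g} > 1.5: reference panel is likely "
            "mis-specified for this sample's variant"
        )
    return f


def derive_cutoff(panel: ReferencePanel) -> float:
    """Sex-call cutoff: the %chrY_MF of a pregnancy at F = ``f_assumed``.

    Exact algebraic inverse of :func:`estimate_fetal_fraction`.
    """
    denom = panel.pct_chrY_am - panel.pct_chrY_ff
    if denom <= 0:
        raise ValueError("degenerate panel: %chrY_AM must exceed %chrY_FF")
    return panel.f_assumed * denom + panel.pct_chrY_ff


def classify_sex(pct_chrY: float, cutoff: float) -> str:
    """"male" iff the chrY percentage reaches the cutoff (tie calls male)."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    return "male" if pct_chrY >= cutoff else "female"


def flag_turner(
    pct_chrX: float,
    female_ref_mean: float,
    female_ref_sd: float,
    call: str,
    z_threshold: float = -3.0,
) -> set[str]:
    """Flag suspected monosomy X (Turner syndrome, 45,X).

    A Turner fetus is called female (it has no chrY), but its chrX dosage is
    depleted relative to a normal-female reference. The flag fires when the
    sample's chrX percentage lies more than ``|z_threshold|`` reference SDs
    below the female reference mean, and only on female calls.
    """
    if female_ref_sd <= 0:
        raise ValueError("female_ref_sd must be positive")
    if call != "female":
        return set()
    z = (pct_chrX - female_ref_mean) / female_ref_sd
    return {"XO_suspected"} if z < z_threshold else set()


@dataclass
class SexCallResult:
    """Per-sample fetal sex call."""

    sample_id: str
    pct_chrY: float
    call: str
    cutoff_used: float
    variant: str
    fetal_fraction: float | None = None
    sca_flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "pct_chrY": self.pct_chrY,
            "call": self.call,
            "cutoff_used": self.cutoff_used,
            "variant": self.variant,
            "fetal_fraction": self.fetal_fraction,
            "sca_flags": ",".join(sorted(self.sca_flags)),
        }


@dataclass
class CohortEvaluation:
    """Sex-call error rates against known fetal sex.

    FNR = true males called female / true males;
    FPR = true females called male / true females.
    """

    n_samples: int
    n_male_truth: int
    n_female_truth: int
    false_negatives: int
    false_positives: int

    @property
    def fnr(self) -> float:
        return self.false_negatives / self.n_male_truth if self.n_male_truth else 0.0

    @property
    def fpr(self) -> float:
        return self.false_positives / self.n_female_truth if self.n_female_truth else 0.0

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_male_truth": self.n_male_truth,
            "n_female_truth": self.n_female_truth,
            "false_negatives": self.false_negatives,
            "false_positives": self.false_positives,
            "fnr": self.fnr,
            "fpr": self.fpr,
        }


def evaluate_cohort(
    calls: Sequence[SexCallResult], truth: Mapping[str, str]
) -> CohortEvaluation:
    """Score calls against known fetal sex (XO counts as female truth)."""
    fn = fp = n_male = n_female = 0
    for result in calls:
        if result.sample_id not in truth:
            raise KeyError(f"no truth label for sample {result.sample_id!r}")
        true_sex = truth[result.sample_id].lower()
        if true_sex in ("male", "m"):
            n_male += 1
            if result.call == "female":
                fn += 1
        elif true_sex in ("female", "f", "xo"):
            n_female += 1
            if result.call == "male":
                fp += 1
        else:
            raise ValueError(f"unrecognized truth label {truth[result.sample_id]!r}")
    return CohortEvaluation(
        n_samples=len(calls),
        n_male_truth=n_male,
        n_female_truth=n_female,
        false_negatives=fn,
        false_positives=fp,
    )


class FetalSexClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier on the chrY UMR percentage.

    ``fit(X, y)`` learns the reference panel from a 1-D feature of chrY
    percentages: samples labelled ``"female_fetus"`` supply the background
    median %chrY_FF, samples labelled ``"adult_male"`` the full-male median
    %chrY_AM; the cutoff is placed at the assumed minimal fetal fraction.
    Alternatively pass a ready ``panel`` (a :class:`ReferencePanel` or a name
    in :data:`PANELS`) and call ``predict`` without fitting data-dependent
    state beyond validation.

    ``predict(X)`` returns "male"/"female" per sample;
    ``predict_fetal_fraction(X)`` the formula-based fetal fraction estimate.
    """

    def __init__(self, f_assumed: float = 0.01, panel: ReferencePanel | str | None = None):
        self.f_assumed = f_assumed
        self.panel = panel

    def _resolve_panel(self) -> ReferencePanel | None:
        if isinstance(self.panel, str):
            try:
                return PANELS[self.panel]
            except KeyError:
                raise ValueError(
                    f"unknown panel {self.panel!r}; available: {sorted(PANELS)}"
                ) from None
        return self.panel

    def fit(self, X, y=None) -> "FetalSexClassifier":
        X = np.asarray(X, dtype=float).reshape(-1)
        preset = self._resolve_panel()
        if preset is not None:
            self.panel_ = preset
        else:
            if y is None:
                raise ValueError("y labels required when no preset panel is given")
            y = np.asarray(y, dtype=object).reshape(-1)
            if len(y) != len(X):
                raise ValueError("X and y length mismatch")
            ff = X[y == "female_fetus"]
            am = X[y == "adult_male"]
            if len(ff) == 0 or len(am) == 0:
                raise ValueError(
                    "fit needs both 'female_fetus' and 'adult_male' labelled samples"
                )
            self.panel_ = ReferencePanel.from_cohort(ff, am, f_assumed=self.f_assumed)
        self.cutoff_ = derive_cutoff(self.panel_)
        self.classes_ = np.array(["female", "male"], dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        X = np.asarray(X, dtype=float).reshape(-1)
        return np.where(X >= self.cutoff_, "male", "female").astype(object)

    def predict_fetal_fraction(self, X) -> np.ndarray:
        check_is_fitted(self, "panel_")
        X = np.asarray(X, dtype=float).reshape(-1)
        denom = self.panel_.pct_chrY_am - self.panel_.pct_chrY_ff
        return (X - self.panel_.pct_chrY_ff) / denom

    def score(self, X, y) -> float:
        """Accuracy of the sex call against true labels."""
        y = np.asarray(y, dtype=object).reshape(-1)
        return float(np.mean(self.predict(X) == y))
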