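"""Synthetic microdialysate cohort generator with ground truth.

Emulates the statistical structure the pipeline assumes: a small paired
cohort (cases with up to three catheters: enhancing tumour E, non-enhancing
tumour NE, brain B), positive heavy-tailed peak areas generated by a
log-normal multiplicative model, patient-level heterogeneity that is shared
across a case's catheters (and therefore cancels in within-case fold
changes), location-dependent class effects, intensity-dependent non-detects,
and a block of CSF samples with graded blood contamination.

Metabolite classes and their roles:

* ``plasma_derived`` — elevated in E (disrupted blood-brain barrier), only
  slightly in NE; carried into CSF in proportion to blood contamination.
* ``tumour_produced`` — elevated in both E and NE; one designated
  "GAA-like" member carries an extreme enhancing-tumour effect.
* ``brain_associated`` — elevated in B (an "NAA-like" profile).
* ``idh_oncometabolite`` — a "2-HG-like" metabolite elevated in tumour
  catheters of IDH-mutant cases only.
* ``background`` — no location effect.

All randomness flows from a single seed through named substreams, so any
block (abundances, missingness, CSF) can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    IdhStatus,
    Layer,
    Location,
    PeakAreaMatrix,
    SampleAnnotation,
    ValidationError,
)

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate_cohort", "fixture_small"]

CLASSES = (
    "plasma_derived",
    "tumour_produced",
    "brain_associated",
    "idh_oncometabolite",
    "background",
)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.  Defaults describe a 9-case
    paired cohort (7 cases with E/NE/B catheters, 2 with E/B) of 200
    metabolites plus 28 CSF samples, matching the cohort geometry the
    analysis is designed for."""

    seed: int = 0
    n_cases: int = 9
    #: catheters per case, cycled; default: 7 full triplets then E/B pairs
    catheters_per_case: tuple[tuple[str, ...], ...] = (
        ("E", "NE", "B"),
    ) * 7 + (("E", "B"),) * 2
    n_metabolites: int = 200
    #: class proportions; idh_oncometabolite gets max(1, round(prop*n))
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "plasma_derived": 0.20,
            "tumour_produced": 0.10,
            "brain_associated": 0.10,
            "idh_oncometabolite": 0.005,
            "background": 0.595,
        }
    )
    #: log2-scale location effects per class, relative to brain
    effects_log2: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "plasma_derived": {"E": 3.0, "NE": 0.5, "B": 0.0},
            "tumour_produced": {"E": 5.0, "NE": 3.0, "B": 0.0},
            "brain_associated": {"E": -3.0, "NE": -1.0, "B": 0.0},
            "idh_oncometabolite": {"E": 4.4, "NE": 4.4, "B": 0.0},
            "background": {"E": 0.0, "NE": 0.0, "B": 0.0},
        }
    )
    #: extreme enhancing effect for the designated GAA-like metabolite
    gaa_like_log2: dict[str, float] = field(
        default_factory=lambda: {"E": 7.0, "NE": 3.75, "B": 0.0}
    )
    #: fraction of cases that are IDH-mutant (first ones in order)
    idh_mutant_fraction: float = 0.5
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    patient_sd_log2: float = 1.0   # tau: per-(metabolite, case) shift
    noise_sd_log2: float = 0.5     # sigma: per-cell residual
    missing_rate: float = 0.05
    missing_mechanism: str = "intensity_dependent"  # or "random"
    n_batches: int = 2
    #: perfusate contamination: this many cases get the designated
    #: "lactate-like" background metabolite flagged as excluded
    n_perfusate_excluded_cases: int = 2
    # CSF block
    n_csf: int = 28                # first two form the paired bloody/clean pair
    csf_paired_contamination: tuple[float, float] = (0.8, 0.005)
    csf_contamination_range: tuple[float, float] = (0.0, 0.9)
    csf_plasma_boost_log2: float = 4.0   # plasma-profile elevation of plasma class
    csf_noise_sd_log2: float = 0.3
    heme_scale: float = 1000.0

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_metabolites < 10:
            raise ValidationError("need >= 1 case and >= 10 metabolites")
        if not self.catheters_per_case or any(
            len(c) == 0 for c in self.catheters_per_case
        ):
            raise ValidationError("each case needs at least one catheter")
        bad = [loc for c in self.catheters_per_case for loc in c
               if loc not in ("E", "NE", "B")]
        if bad:
            raise ValidationError(f"unknown catheter locations: {bad}")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValidationError("class proportions must sum to 1")
        if min(self.patient_sd_log2, self.noise_sd_log2, self.csf_noise_sd_log2) < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        for f in (*self.csf_paired_contamination, *self.csf_contamination_range):
            if not 0 <= f <= 1:
                raise ValidationError("contamination fractions must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth: per-metabolite class and realized log2 effects,
    per-case IDH status, per-CSF-sample contamination fraction."""

    metabolite_class: pd.Series         # metabolite -> class
    effects_log2: pd.DataFrame          # metabolite x (E, NE, B)
    idh_status: pd.Series               # case -> mutant/wild_type
    csf_contamination: pd.Series        # CSF sample -> fraction
    special: dict[str, str]             # role -> metabolite id


def _substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _apply_missing(
    values: np.ndarray, rate: float, mechanism: str, rng: np.random.Generator
) -> np.ndarray:
    """Return values with NaN non-detects.  ``intensity_dependent`` drops
    preferentially low values via a logistic in log-abundance centred at
    the rate-quantile (realized rate approximates the nominal one);
    ``random`` is uniform Bernoulli."""
    if rate == 0:
        return values
    if mechanism == "random":
        mask = rng.random(values.shape) < rate
    elif mechanism == "intensity_dependent":
        logv = np.log2(values)
        centre = np.quantile(logv, rate)
        p = 1.0 / (1.0 + np.exp((logv - centre) / 0.5))
        mask = rng.random(values.shape) < p
    else:
        raise ValidationError(f"unknown missingness mechanism {mechanism!r}")
    out = values.copy()
    out[mask] = np.nan
    return out


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[PeakAreaMatrix, SampleAnnotation, SyntheticTruth]:
    """Generate (raw peak-area matrix incl. CSF samples, annotation, truth).

    value(m, s) = 2 ** (mu_m + patient_{m,case} + effect_{m,loc} + eps),
    eps ~ N(0, sigma^2), patient effects ~ N(0, tau^2) per (metabolite,
    case) shared across the case's catheters.  CSF samples mix a plasma
    profile into a clean-CSF profile proportionally to the contamination
    fraction, with heme content monotone in that fraction.
    """
    config.validate()
    cfg = config
    rngs = _substreams(cfg.seed, [
        "classes", "baseline", "patient", "noise", "missing",
        "csf_profile", "csf_noise", "csf_missing", "heme",
    ])

    # --- metabolite classes -------------------------------------------------
    n = cfg.n_metabolites
    counts = {}
    for cls in CLASSES[:-1]:
        prop = cfg.class_proportions.get(cls, 0.0)
        counts[cls] = max(1, round(prop * n)) if cls == "idh_oncometabolite" and prop > 0 else round(prop * n)
    counts["background"] = n - sum(counts.values())
    if counts["background"] < 1:
        raise ValidationError("class proportions leave no background metabolites")
    labels = np.array(
        sum(([cls] * counts[cls] for cls in CLASSES), []), dtype=object
    )
    rngs["classes"].shuffle(labels)
    met_ids = [f"met_{i:04d}" for i in range(1, n + 1)]
    met_class = pd.Series(labels, index=met_ids, name="class")

    special: dict[str, str] = {}
    tumour_ids = list(met_class.index[met_class == "tumour_produced"])
    if tumour_ids:
        special["gaa_like"] = tumour_ids[0]
    idh_ids = list(met_class.index[met_class == "idh_oncometabolite"])
    if idh_ids:
        special["2hg_like"] = idh_ids[0]
    brain_ids = list(met_class.index[met_class == "brain_associated"])
    if brain_ids:
        special["naa_like"] = brain_ids[0]
    bg_ids = list(met_class.index[met_class == "background"])
    if bg_ids and cfg.n_perfusate_excluded_cases > 0:
        special["lactate_like"] = bg_ids[0]

    # --- effect table (log2) ------------------------------------------------
    eff = pd.DataFrame(0.0, index=met_ids, columns=["E", "NE", "B"])
    for cls in CLASSES:
        for loc in ("E", "NE", "B"):
            eff.loc[met_class == cls, loc] = cfg.effects_log2[cls][loc]
    if "gaa_like" in special:
        for loc in ("E", "NE", "B"):
            eff.loc[special["gaa_like"], loc] = cfg.gaa_like_log2[loc]

    # --- cases, samples, annotation ----------------------------------------
    cases = [f"case{i:02d}" for i in range(1, cfg.n_cases + 1)]
    n_mut = round(cfg.idh_mutant_fraction * cfg.n_cases)
    # interleave mutant cases across the enrolment (and hence batch) order,
    # as in a trial accruing both genotypes throughout
    statuses = np.array([IdhStatus.WILD_TYPE.value] * cfg.n_cases, dtype=object)
    if n_mut > 0:
        spread = np.round(np.linspace(0, cfg.n_cases - 1, n_mut)).astype(int)
        statuses[spread] = IdhStatus.MUTANT.value
    idh = pd.Series(list(statuses), index=cases, name="idh_status")
    catheter_letter = {"E": "X", "NE": "Y", "B": "Z"}
    samples, ann_rows = [], []
    for i, case in enumerate(cases):
        locs = cfg.catheters_per_case[i % len(cfg.catheters_per_case)]
        batch = str(1 + (i * cfg.n_batches) // cfg.n_cases) if cfg.n_batches > 1 else "1"
        for loc in locs:
            sid = f"{case}_{loc}"
            samples.append((sid, case, loc, batch))
            ann_rows.append({
                "sample_id": sid, "case_id": case,
                "catheter": catheter_letter[loc], "location": loc,
                "idh_status": idh[case], "recurrent": False,
                "batch": batch, "heme": np.nan,
                "perfusate_excluded": frozenset(),
            })

    # perfusate exclusions: lactate-like analyte in the first k cases
    if "lactate_like" in special:
        k = min(cfg.n_perfusate_excluded_cases, cfg.n_cases)
        flagged = set(cases[:k])
        for row in ann_rows:
            if row["case_id"] in flagged:
                row["perfusate_excluded"] = frozenset({special["lactate_like"]})

    # --- microdialysate abundances ------------------------------------------
    mu = cfg.baseline_log2_mean + cfg.baseline_log2_sd * rngs["baseline"].standard_normal(n)
    # the designated marquee metabolites emulate compounds that are part of
    # the >=90%-presence universe: pin their baseline comfortably above the
    # detection floor so they are not lost to intensity-dependent non-detects
    for sid in special.values():
        mu[met_ids.index(sid)] = cfg.baseline_log2_mean + cfg.baseline_log2_sd
    patient = cfg.patient_sd_log2 * rngs["patient"].standard_normal((n, cfg.n_cases))
    case_index = {c: j for j, c in enumerate(cases)}
    log2_vals = np.empty((n, len(samples)))
    idh_col = eff.index.get_indexer([special["2hg_like"]])[0] if "2hg_like" in special else -1
    for j, (sid, case, loc, _batch) in enumerate(samples):
        e = eff[loc].to_numpy().copy()
        if idh_col >= 0 and idh[case] != IdhStatus.MUTANT.value:
            e[idh_col] = 0.0  # oncometabolite effect only in IDH-mutant cases
        log2_vals[:, j] = mu + patient[:, case_index[case]] + e
    log2_vals += cfg.noise_sd_log2 * rngs["noise"].standard_normal(log2_vals.shape)
    values = np.exp2(log2_vals)
    values = _apply_missing(values, cfg.missing_rate, cfg.missing_mechanism,
                            rngs["missing"])

    # --- CSF block ------------------------------------------------------------
    csf_ids: list[str] = []
    contamination: list[float] = []
    if cfg.n_csf >= 2:
        csf_ids = ["csf_pair_bloody", "csf_pair_clean"] + [
            f"csf_{i:02d}" for i in range(1, cfg.n_csf - 1)
        ]
        lo, hi = cfg.csf_contamination_range
        pooled = np.linspace(lo, hi, cfg.n_csf - 2) if cfg.n_csf > 2 else []
        contamination = [*cfg.csf_paired_contamination, *pooled]
    elif cfg.n_csf == 1:
        csf_ids = ["csf_01"]
        contamination = [cfg.csf_contamination_range[0]]

    csf_vals = None
    if csf_ids:
        prof = rngs["csf_profile"]
        # clean CSF: brain-flavoured; tumour products scarce
        clean_shift = np.where(
            met_class == "brain_associated", 1.0,
            np.where(met_class == "tumour_produced", -4.0, 0.0),
        ) + 0.25 * prof.standard_normal(n)
        clean = np.exp2(mu + clean_shift)
        plasma_shift = np.where(met_class == "plasma_derived",
                                cfg.csf_plasma_boost_log2, 0.0)
        plasma = np.exp2(mu + plasma_shift + 0.25 * prof.standard_normal(n))
        f = np.array(contamination)
        mix = clean[:, None] * (1 - f[None, :]) + plasma[:, None] * f[None, :]
        mix *= np.exp2(cfg.csf_noise_sd_log2
                       * rngs["csf_noise"].standard_normal(mix.shape))
        csf_vals = _apply_missing(mix, cfg.missing_rate, cfg.missing_mechanism,
                                  rngs["csf_missing"])
        heme = cfg.heme_scale * f * (1.0 + 0.01 * rngs["heme"].random(f.size))
        heme += 0.1 * rngs["heme"].random(f.size)  # clean CSF still has trace heme
        for i, sid in enumerate(csf_ids):
            subject = "csf_pair_subject" if sid.startswith("csf_pair") else f"csf_subject_{sid[-2:]}"
            ann_rows.append({
                "sample_id": sid, "case_id": subject,
                "catheter": "none", "location": Location.CSF.value,
                "idh_status": IdhStatus.UNKNOWN.value, "recurrent": False,
                "batch": "csf", "heme": float(heme[i]),
                "perfusate_excluded": frozenset(),
            })

    all_ids = [s[0] for s in samples] + csf_ids
    data = values if csf_vals is None else np.concatenate([values, csf_vals], axis=1)
    frame = pd.DataFrame(data, index=met_ids, columns=all_ids)
    batch_of = {s[0]: s[3] for s in samples}
    batch_of.update({sid: "csf" for sid in csf_ids})
    matrix = PeakAreaMatrix(values=frame, layer=Layer.RAW, batch_of=batch_of)
    annotation = SampleAnnotation(pd.DataFrame(ann_rows).set_index("sample_id"))
    truth = SyntheticTruth(
        metabolite_class=met_class,
        effects_log2=eff,
        idh_status=idh,
        csf_contamination=pd.Series(contamination, index=csf_ids, dtype=float),
        special=special,
    )
    return matrix, annotation, truth


FIXTURE_SEED = 20230620


def fixture_small(seed: int = FIXTURE_SEED):
    """The deterministic miniature cohort used across the test suite:
    9 cases (7 with E/NE/B, 2 with E/B), 200 metabolites, 28 CSF samples.
    Byte-stable across runs for a given seed."""
    return generate_cohort(GeneratorConfig(seed=seed))
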