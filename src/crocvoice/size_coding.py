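"""Acoustic space construction and size-coding statistics.

The 13 per-call descriptors (five pitch, eight spectral) are standardized
and reduced by PCA to two Acoustic Dimensions.  AD1 typically captures the
distribution of spectral energy and AD2 the call pitch.  Linear mixed models
with a per-individual random intercept then test whether the AD scores carry
body-size information: for each dimension, likelihood-ratio tests of the
size, species and size-by-species terms compare maximum-likelihood fits of
nested models.  Per-species allometric regressions on individual means are
fitted by OLS and compared through a pooled two-line model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .audio_io import Waveform
from .pitch_tracking import (
    UnvoicedCallError,
    correct_octave_jumps,
    extract_f0_contour,
    summarize_contour,
)
from .spectral_features import SpectrumConfig, compute_mean_spectrum, spectral_descriptors

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "AcousticSpace",
    "SizeCodingResult",
    "extract_call_features",
    "assemble_feature_matrix",
    "fit_acoustic_space",
    "test_size_effect",
    "regress_and_compare_lines",
]

#: the 13 analysis variables, in canonical order
FEATURE_COLUMNS = [
    "mean_pitch", "start_pitch", "max_pitch", "min_pitch", "end_pitch",
    "mode_freq", "q25", "q75", "iqr", "centroid", "skewness", "kurtosis", "sfm",
]


@dataclass
class AcousticSpace:
    """PCA of the standardized 13-descriptor matrix, first two components.

    Loadings are unit-norm eigenvector columns (13 x 2); scores are per-call
    coordinates on AD1/AD2; individual scores are per-individual means.
    Signs are fixed so the centroid loads positively on AD1 and mean pitch
    positively on AD2.
    """

    loadings: pd.DataFrame
    explained_variance: tuple[float, float]
    call_scores: pd.DataFrame
    individual_scores: pd.DataFrame
    column_means: np.ndarray
    column_sds: np.ndarray


@dataclass
class SizeCodingResult:
    """LRT statistics per (dimension, term) plus per-species regression lines."""

    tests: pd.DataFrame  # columns: dimension, term, chi_square, df, p_value
    regressions: pd.DataFrame | None = None
    line_comparison: pd.DataFrame | None = None


def extract_call_features(
    waveform: Waveform,
    spectrum_config: SpectrumConfig = SpectrumConfig(),
    **tracker_kwargs,
) -> dict[str, float]:
    """The 13 descriptors of one call (raises UnvoicedCallError on silence)."""
    contour = correct_octave_jumps(extract_f0_contour(waveform, **tracker_kwargs))
    pitch = summarize_contour(contour)
    spec = spectral_descriptors(compute_mean_spectrum(waveform, spectrum_config))
    return {
        "mean_pitch": pitch.mean_pitch,
        "start_pitch": pitch.start_pitch,
        "max_pitch": pitch.max_pitch,
        "min_pitch": pitch.min_pitch,
        "end_pitch": pitch.end_pitch,
        "mode_freq": spec.mode_freq,
        "q25": spec.q25,
        "q75": spec.q75,
        "iqr": spec.iqr,
        "centroid": spec.centroid,
        "skewness": spec.skewness,
        "kurtosis": spec.kurtosis,
        "sfm": spec.sfm,
    }


def assemble_feature_matrix(
    calls: list[tuple[str, str, Waveform]],
    metadata: pd.DataFrame,
    spectrum_config: SpectrumConfig = SpectrumConfig(),
    **tracker_kwargs,
) -> pd.DataFrame:
    """Extract features for (call_id, individual_id, waveform) triples.

    Every call must map to a metadata row (individual_id, species,
    body_length_cm); duplicate metadata ids or orphan calls raise.  Calls
    whose extraction fails (e.g. unvoiced) are dropped with a logged reason.
    Returns a row-aligned frame of features plus covariates.
    """
    if metadata["individual_id"].duplicated().any():
        dupes = metadata.loc[metadata["individual_id"].duplicated(), "individual_id"]
        raise ValueError(f"duplicate metadata ids: {sorted(set(dupes))}")
    meta = metadata.set_index("individual_id")
    rows = []
    for call_id, individual_id, wav in calls:
        if individual_id not in meta.index:
            raise ValueError(f"call {call_id!r} names unknown individual {individual_id!r}")
        try:
            feats = extract_call_features(wav, spectrum_config, **tracker_kwargs)
        except (UnvoicedCallError, ValueError) as exc:
            logger.warning("dropping call %s: %s", call_id, exc)
            continue
        feats.update(
            call_id=call_id,
            individual_id=individual_id,
            species=meta.at[individual_id, "species"],
            body_length_cm=float(meta.at[individual_id, "body_length_cm"]),
        )
        rows.append(feats)
    cols = ["call_id", "individual_id", "species", "body_length_cm", *FEATURE_COLUMNS]
    return pd.DataFrame(rows, columns=cols)


def fit_acoustic_space(features: pd.DataFrame) -> AcousticSpace:
    """Correlation-matrix PCA of the 13 descriptors, two components retained.

    Columns are standardized (the descriptors mix Hz and dimensionless
    units); a constant column is an error naming the descriptor.  Requires
    more calls than variables.
    """
    x = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    if x.shape[0] <= len(FEATURE_COLUMNS):
        raise ValueError("need more calls than descriptors to fit the acoustic space")
    if np.isnan(x).any():
        raise ValueError("feature matrix contains missing values")
    sds = x.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [c for c, s in zip(FEATURE_COLUMNS, sds) if s == 0]
        raise ValueError(f"constant descriptor column(s): {bad}")
    means = x.mean(axis=0)
    z = (x - means) / sds
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.T.copy()  # 13 x 2 unit-norm columns
    # sign convention: centroid positive on AD1, mean pitch positive on AD2
    i_cent = FEATURE_COLUMNS.index("centroid")
    i_pitch = FEATURE_COLUMNS.index("mean_pitch")
    for j, i_ref in enumerate((i_cent, i_pitch)):
        if loadings[i_ref, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    explained = pca.explained_variance_ratio_
    call_scores = pd.DataFrame(
        {
            "call_id": features["call_id"].to_numpy()
            if "call_id" in features else np.arange(len(features)),
            "individual_id": features["individual_id"].to_numpy()
            if "individual_id" in features else np.arange(len(features)),
            "AD1": scores[:, 0],
            "AD2": scores[:, 1],
        }
    )
    individual_scores = (
        call_scores.groupby("individual_id", sort=True)[["AD1", "AD2"]]
        .mean()
        .reset_index()
    )
    return AcousticSpace(
        loadings=pd.DataFrame(loadings, index=FEATURE_COLUMNS, columns=["AD1", "AD2"]),
        explained_variance=(float(explained[0]), float(explained[1])),
        call_scores=call_scores,
        individual_scores=individual_scores,
        column_means=means,
        column_sds=sds,
    )


def _fit_mixed_ml(formula: str, data: pd.DataFrame, groups: str) -> float:
    """Maximum-likelihood log-likelihood of a random-intercept mixed model."""
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.mixedlm(formula, data, groups=data[groups])
        try:
            fit = model.fit(reml=False, method="lbfgs")
        except Exception:
            fit = model.fit(reml=False)
        if getattr(fit, "converged", True) is False:
            fit = model.fit(reml=False, method="powell")
    return float(fit.llf)


def test_size_effect(
    scores: pd.DataFrame,
    terms: tuple[str, ...] = ("size", "species", "size_x_species"),
    dimensions: tuple[str, ...] = ("AD1", "AD2"),
) -> SizeCodingResult:
    """Likelihood-ratio tests of size, species and their interaction.

    ``scores`` needs columns body_length_cm, species, individual_id and the
    requested score ``dimensions``.  For each dimension: the size and species
    main effects are tested by dropping them from the additive model, the
    interaction by comparing the full crossed model against the additive one.
    All fits are maximum likelihood with a per-individual random intercept;
    chi-square = 2 * (loglik_full - loglik_reduced), df = parameter
    difference.
    """
    data = scores.copy()
    species = sorted(data["species"].unique())
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    unknown = set(terms) - {"size", "species", "size_x_species"}
    if unknown:
        raise ValueError(f"unknown terms {sorted(unknown)}")
    k = len(species)
    rows = []
    for ad in dimensions:
        cache: dict[str, float] = {}

        def ll(formula: str, ad=ad, cache=cache) -> float:
            if formula not in cache:
                cache[formula] = _fit_mixed_ml(f"{ad} ~ {formula}", data,
                                               "individual_id")
            return cache[formula]

        plans = {
            "size": ("body_length_cm + C(species)", "C(species)", 1),
            "species": ("body_length_cm + C(species)", "body_length_cm", k - 1),
            "size_x_species": ("body_length_cm * C(species)",
                               "body_length_cm + C(species)", k - 1),
        }
        for term in terms:
            full, reduced, df = plans[term]
            chi2 = max(0.0, 2.0 * (ll(full) - ll(reduced)))
            rows.append(
                {
                    "dimension": ad,
                    "term": term,
                    "chi_square": chi2,
                    "df": df,
                    "p_value": float(stats.chi2.sf(chi2, df)),
                }
            )
    return SizeCodingResult(tests=pd.DataFrame(rows))


def regress_and_compare_lines(
    values: pd.DataFrame,
    response: str,
    species_pair: tuple[str, str],
) -> SizeCodingResult:
    """Per-species OLS of an individual-mean descriptor on body length.

    ``values`` needs one row per individual with columns species,
    body_length_cm and ``response``.  The two species' lines are compared in
    a pooled model ``response ~ length * species`` with length centered on
    the pooled mean: the species main effect then tests the vertical offset
    between the lines at a typical length (the intercept difference), and
    the interaction tests the slope difference (t statistics and p-values).
    Per-species slopes and intercepts are reported on the raw scale.
    """
    import statsmodels.formula.api as smf

    sub = values[values["species"].isin(species_pair)].copy()
    for sp in species_pair:
        if (sub["species"] == sp).sum() < 3:
            raise ValueError(f"need >= 3 individuals for species {sp!r}")
    reg_rows = []
    for sp in species_pair:
        grp = sub[sub["species"] == sp]
        fit = smf.ols(f"{response} ~ body_length_cm", grp).fit()
        reg_rows.append(
            {
                "species": sp,
                "slope": float(fit.params["body_length_cm"]),
                "slope_se": float(fit.bse["body_length_cm"]),
                "intercept": float(fit.params["Intercept"]),
                "intercept_se": float(fit.bse["Intercept"]),
                "n": int(fit.nobs),
            }
        )
    sub["species"] = pd.Categorical(sub["species"], categories=list(species_pair))
    sub["length_c"] = sub["body_length_cm"] - sub["body_length_cm"].mean()
    pooled = smf.ols(f"{response} ~ length_c * C(species)", sub).fit()
    sp_term = f"C(species)[T.{species_pair[1]}]"
    comparison = pd.DataFrame(
        [
            {
                "quantity": "intercept_difference",
                "t": float(pooled.tvalues[sp_term]),
                "p_value": float(pooled.pvalues[sp_term]),
            },
            {
                "quantity": "slope_difference",
                "t": float(pooled.tvalues[f"length_c:{sp_term}"]),
                "p_value": float(pooled.pvalues[f"length_c:{sp_term}"]),
            },
        ]
    )
    return SizeCodingResult(
        tests=pd.DataFrame(columns=["dimension", "term", "chi_square", "df", "p_value"]),
        regressions=pd.DataFrame(reg_rows),
        line_comparison=comparison,
    )
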