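"""Distribution summaries and label/sign correlation for rotation data.

These are the bulk-statistics companions to the classification work: the
z-filtered four-moment summary of a specific-rotation distribution, a census
of extreme rotations (|value| beyond a threshold), and the Pearson
correlation between R/S configuration and rotation sign (which, on the real
data, is indistinguishable from zero -- configuration labels and rotation
signs are uncorrelated across molecules).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

logger = logging.getLogger(__name__)


@dataclass
class DistributionSummary:
    """Four moments of a (possibly z-filtered) sample.

    Kurtosis is in the excess (Fisher) convention: 0 for a normal
    distribution.  ``n_used + n_filtered`` equals the input size.
    """

    n_used: int
    n_filtered: int
    mean: float
    std: float
    skewness: float
    kurtosis: float
    wavelength: float | None = None
    class_tag: str | None = None


def describe(
    values,
    z_cut: float = 3.0,
    wavelength: float | None = None,
    class_tag: str | None = None,
) -> DistributionSummary:
    """Moments after a single-pass ``|z| > z_cut`` outlier filter.

    z-scores are computed once from the *unfiltered* mean and standard
    deviation (no iteration), so the result does not depend on the order in
    which points would be removed.  ``z_cut=inf`` disables filtering.  The
    reported standard deviation uses the sample (ddof=1) convention;
    skewness and excess kurtosis use the conventional biased estimators.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if np.isfinite(z_cut):
        mu, sd = x.mean(), x.std(ddof=0)
        if sd == 0:
            kept = x
        else:
            kept = x[np.abs((x - mu) / sd) <= z_cut]
    else:
        kept = x
    n_filtered = len(x) - len(kept)
    if n_filtered:
        logger.info("describe: filtered %d of %d values at |z| > %g", n_filtered, len(x), z_cut)
    if len(kept) < 4:
        raise ValueError(f"only {len(kept)} values survive the z filter; need >= 4 for kurtosis")
    if kept.std(ddof=0) == 0:
        raise ValueError("zero variance after filtering: skewness and kurtosis are undefined")
    return DistributionSummary(
        n_used=len(kept),
        n_filtered=n_filtered,
        mean=float(kept.mean()),
        std=float(kept.std(ddof=1)),
        skewness=float(sstats.skew(kept)),
        kurtosis=float(sstats.kurtosis(kept, fisher=True)),
        wavelength=wavelength,
        class_tag=class_tag,
    )


def outlier_census(values, threshold: float = 1000.0) -> tuple[float, float]:
    """(fraction of |value| > threshold, maximum |value|)."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("outlier_census needs at least one value")
    a = np.abs(x)
    return float(np.mean(a > threshold)), float(a.max())


def label_sign_correlation(labels, rotations) -> tuple[float, float]:
    """Pearson r (and two-sided non-correlation p-value) of R/S vs rotation sign.

    Labels may be "R"/"S" strings or +/-1; R maps to +1.  Rotation values are
    reduced to their sign; exact zeros carry no sign and are excluded with a
    log record.
    """
    lab = np.asarray(labels)
    rot = np.asarray(rotations, dtype=float)
    if len(lab) != len(rot):
        raise ValueError(f"{len(lab)} labels vs {len(rot)} rotations")
    if lab.dtype.kind in ("U", "S", "O"):
        unknown = set(lab.tolist()) - {"R", "S"}
        if unknown:
            raise ValueError(f"labels must be 'R'/'S', got extra values {unknown}")
        enc = np.where(lab == "R", 1.0, -1.0)
    else:
        enc = lab.astype(float)
        if not np.all(np.isin(enc, (-1.0, 1.0))):
            raise ValueError("numeric labels must be +/-1")
    keep = rot != 0.0
    if not np.all(keep):
        logger.info("label_sign_correlation: excluding %d zero rotations", int((~keep).sum()))
    enc, rot = enc[keep], rot[keep]
    r, p = sstats.pearsonr(enc, np.sign(rot))
    return float(r), float(p)
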