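"""Microbiome profile matrices, labels, and synthetic cohort generation.

Two profile kinds are supported, mirroring what shotgun-metagenomic
pipelines emit after profiling:

* ``marker`` — binary presence/absence of strain-specific gene markers,
  typically very wide (up to ~10^5 features) and sparse;
* ``abundance`` — species-level relative abundances in [0, 1], a few
  hundred features, each sample summing to 1.

Profiles travel as delimited text: a header row of feature ids and a
first column of sample ids, rows = samples. The synthetic generator
plants a low-rank latent background plus a class-dependent shift so the
whole downstream pipeline (representation learning, classifier
selection, evaluation) can be exercised without any cohort download.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProfileKind",
    "ProfileMatrix",
    "LabelVector",
    "SyntheticSpec",
    "ProfileError",
    "ProfileParseError",
    "ProfileValidationError",
    "load_profiles",
    "save_profiles",
    "load_labels",
    "save_labels",
    "generate_synthetic",
]


class ProfileError(ValueError):
    """Base error for profile handling."""


class ProfileParseError(ProfileError):
    """A cell in a profile file could not be parsed as a number."""


class ProfileValidationError(ProfileError):
    """A profile violates the invariants of its declared kind."""


class ProfileKind(str, enum.Enum):
    MARKER = "marker"
    ABUNDANCE = "abundance"


def _as_kind(kind: "ProfileKind | str") -> ProfileKind:
    return ProfileKind(kind)


@dataclass(frozen=True)
class ProfileMatrix:
    """A validated samples × features profile matrix.

    Parameters
    ----------
    values
        Float matrix of shape (n_samples, n_features); rows are samples.
    sample_ids, feature_ids
        Unique string identifiers for rows and columns.
    kind
        ``marker`` (entries in {0, 1}) or ``abundance`` (entries in [0, 1]).
    """

    values: np.ndarray
    sample_ids: tuple
    feature_ids: tuple
    kind: ProfileKind

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "kind", _as_kind(self.kind))
        self._validate()

    def _validate(self) -> None:
        if self.values.ndim != 2:
            raise ProfileValidationError("profile values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ProfileValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.feature_ids) != p:
            raise ProfileValidationError(
                f"{len(self.feature_ids)} feature ids for {p} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ProfileValidationError("duplicate sample ids")
        if len(set(self.feature_ids)) != p:
            raise ProfileValidationError("duplicate feature ids")
        if not np.all(np.isfinite(self.values)):
            raise ProfileValidationError("profile contains non-finite values")
        if self.kind is ProfileKind.MARKER:
            bad = (self.values != 0) & (self.values != 1)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ProfileValidationError(
                    f"marker profile entry not in {{0, 1}} at sample "
                    f"'{self.sample_ids[i]}', feature '{self.feature_ids[j]}' "
                    f"(value {self.values[i, j]!r})"
                )
        else:
            bad = (self.values < 0) | (self.values > 1)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ProfileValidationError(
                    f"abundance entry outside [0, 1] at sample "
                    f"'{self.sample_ids[i]}', feature '{self.feature_ids[j]}' "
                    f"(value {self.values[i, j]!r})"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def subset(self, row_indices) -> "ProfileMatrix":
        """Row subset by integer index, preserving kind and feature ids."""
        idx = np.asarray(row_indices, dtype=int)
        return ProfileMatrix(
            self.values[idx],
            tuple(self.sample_ids[i] for i in idx),
            self.feature_ids,
            self.kind,
        )


@dataclass(frozen=True)
class LabelVector:
    """Binary labels, one per sample; 1 = patient, 0 = healthy control."""

    labels: np.ndarray
    sample_ids: tuple = ()

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise ProfileValidationError("labels must be a 1-D vector")
        if not np.isin(labels, (0, 1)).all():
            raise ProfileValidationError("labels must be 0 (control) or 1 (patient)")
        object.__setattr__(self, "labels", labels.astype(int))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def __len__(self) -> int:
        return len(self.labels)

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ProfileValidationError(
                "label vector must contain both classes (0 and 1)"
            )


def _delimiter(delimiter: str | None, path) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def load_profiles(path, kind, delimiter: str | None = None) -> ProfileMatrix:
    """Read a delimited profile file (header = feature ids, first column = sample ids).

    The delimiter defaults to comma, or tab for ``.tsv``/``.txt`` paths;
    pass ``delimiter`` explicitly to override. Malformed numeric cells
    raise :class:`ProfileParseError` naming the offending sample/feature;
    values violating the declared kind raise :class:`ProfileValidationError`.
    """
    sep = _delimiter(delimiter, path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
        else:
            continue
        i = int(np.argmax(coerced.isna().to_numpy()))
        raise ProfileParseError(
            f"malformed numeric cell at sample '{df.index[i]}', "
            f"feature '{col}' in {path!s}: {df.iloc[i, j]!r}"
        )
    return ProfileMatrix(values, tuple(df.index), tuple(df.columns), kind)


def save_profiles(profile: ProfileMatrix, path, delimiter: str | None = None) -> None:
    """Write a profile to delimited text, round-trippable by :func:`load_profiles`."""
    sep = _delimiter(delimiter, path)
    df = profile.to_dataframe()
    if profile.kind is ProfileKind.MARKER:
        df = df.astype(int)
    df.to_csv(path, sep=sep, index_label="sample_id")


def load_labels(path, sample_ids=None) -> LabelVector:
    """Read labels: either one {0,1} per line, or two columns ``sample_id,label``.

    With the two-column form and ``sample_ids`` given, labels are reordered
    to match the profile's sample order.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ProfileParseError(f"empty label file {path!s}")
    two_col = ("," in lines[0]) or ("\t" in lines[0])
    if two_col:
        sep = "," if "," in lines[0] else "\t"
        pairs = {}
        for ln in lines:
            sid, _, lab = (x.strip() for x in ln.replace(sep, "|").partition("|"))
            pairs[sid] = _parse_label(lab, path)
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in pairs]
            if missing:
                raise ProfileValidationError(
                    f"labels missing for samples {missing[:5]} in {path!s}"
                )
            return LabelVector(
                np.array([pairs[s] for s in sample_ids]), tuple(sample_ids)
            )
        return LabelVector(np.array(list(pairs.values())), tuple(pairs))
    labels = np.array([_parse_label(ln, path) for ln in lines])
    return LabelVector(labels, tuple(sample_ids) if sample_ids is not None else ())


def _parse_label(token: str, path) -> int:
    if token not in ("0", "1"):
        raise ProfileParseError(f"label {token!r} in {path!s} is not 0 or 1")
    return int(token)


def save_labels(labels: LabelVector, path) -> None:
    with open(path, "w") as fh:
        if labels.sample_ids:
            for sid, lab in zip(labels.sample_ids, labels.labels):
                fh.write(f"{sid},{lab}\n")
        else:
            for lab in labels.labels:
                fh.write(f"{lab}\n")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic cohort with planted low-dimensional structure.

    ``effect_size`` scales the class-dependent shift applied (on the logit
    or log-abundance scale) to the 10% of features that carry disease
    signal; 0 means labels are independent of the features. ``sparsity``
    is the target overall fraction of 1s for marker profiles.
    """

    n_samples: int
    n_features: int
    latent_dim: int = 8
    effect_size: float = 1.0
    sparsity: float = 0.1
    kind: ProfileKind = ProfileKind.MARKER
    seed: int = 0
    # fraction of features carrying the class effect
    effect_fraction: float = field(default=0.1, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "kind", _as_kind(self.kind))
        if self.n_samples < 1 or self.n_features < 1:
            raise ProfileValidationError("n_samples and n_features must be positive")
        if not (0 < self.latent_dim < self.n_features):
            raise ProfileValidationError("latent_dim must be in (0, n_features)")
        if self.effect_size < 0:
            raise ProfileValidationError("effect_size must be non-negative")
        if not (0 < self.sparsity < 1):
            raise ProfileValidationError("sparsity must be in (0, 1)")
        if not (0 < self.effect_fraction <= 1):
            raise ProfileValidationError("effect_fraction must be in (0, 1]")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


def _calibrate_intercepts(logits: np.ndarray, target: float, iters: int = 60):
    """Per-feature intercepts b_j with mean_i sigmoid(logits[i,j] + b_j) = target.

    Vectorized bisection; the realized mean is monotone in b_j so 60
    halvings pin each intercept far below float precision of the target.
    """
    lo = np.full(logits.shape[1], -40.0)
    hi = np.full(logits.shape[1], 40.0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        mean = _sigmoid(logits + mid).mean(axis=0)
        hi = np.where(mean > target, mid, hi)
        lo = np.where(mean > target, lo, mid)
    return 0.5 * (lo + hi)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def generate_synthetic(spec: SyntheticSpec) -> tuple[ProfileMatrix, LabelVector]:
    """Generate a (profile, labels) pair with planted class structure.

    The generative model: each sample carries latent factors
    z ~ N(0, I_k) that induce correlated low-rank background structure
    in the features; the binary label is drawn from an independent
    standard-normal score thresholded at zero (≈ balanced classes), so
    the only feature–label coupling is an additive class shift of scale
    ``effect_size`` on a fixed random subset of features.

    * marker: feature j of sample i is Bernoulli with success probability
      sigmoid(a_j·z_i + effect_size·v_j·y_i + b_j), with intercepts b_j
      calibrated by bisection so the overall fraction of 1s matches
      ``sparsity``.
    * abundance: row i is the softmax of (a_j·z_i + effect_size·v_j·y_i + ε_ij),
      hence non-negative with rows summing to 1.

    Identical specs (including seed) yield bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_samples, spec.n_features, spec.latent_dim

    z = rng.standard_normal((n, k))
    loadings = rng.standard_normal((k, p)) / np.sqrt(k)

    # independent label score: class membership is pure coin-flip noise
    # unless effect_size couples it into the features below
    label_score = rng.standard_normal(n) + rng.standard_normal(n)
    labels = (label_score > 0).astype(int)

    n_active = max(1, int(round(spec.effect_fraction * p)))
    active = rng.choice(p, size=n_active, replace=False)
    v = np.zeros(p)
    v[active] = rng.standard_normal(n_active)

    logits = z @ loadings + spec.effect_size * np.outer(labels, v)

    sample_ids = tuple(f"S{i:05d}" for i in range(n))
    feature_ids = tuple(f"F{j:05d}" for j in range(p))

    if spec.kind is ProfileKind.MARKER:
        intercepts = _calibrate_intercepts(logits, spec.sparsity)
        probs = _sigmoid(logits + intercepts)
        values = (rng.random((n, p)) < probs).astype(float)
    else:
        noisy = logits + rng.standard_normal((n, p))
        noisy -= noisy.max(axis=1, keepdims=True)
        expo = np.exp(noisy)
        values = expo / expo.sum(axis=1, keepdims=True)

    profile = ProfileMatrix(values, sample_ids, feature_ids, spec.kind)
    return profile, LabelVector(labels, sample_ids)
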