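"""Spectral signatures, the similarity index, OLS unmixing, and compensation.

Spectral cytometers record every fluorophore across all detectors (48 on the
four-laser instrument modelled here) rather than at a single bandpass.  Each
fluorophore is characterised by its *spectral signature* -- its normalized
emission profile over the detector array -- and a cell's detector readout is
modelled as a linear mixture

    y = M a + autofluorescence + noise,

where the columns of M are the signatures and ``a`` the per-fluorophore
abundances.  Unmixing solves the unconstrained ordinary-least-squares problem
``min_a ||M a - y||^2`` per event; negative abundances are retained, not
clipped.  Cellular autofluorescence is handled by appending the unlabeled
control's spectrum as one extra endmember, so its abundance is estimated and
removed from the marker estimates.

The *similarity index* between two signatures is the cosine of their
unit-norm profiles: 0 for spectrally disjoint dyes, 1 for identical spectra.
Pairs above a compatibility threshold (0.98 by convention) cannot be reliably
unmixed together.

Residual cross-channel spillover after unmixing can be corrected with a
percent-coefficient compensation matrix (diagonal 100), applied
multiplicatively through its inverse -- the vendor convention for values such
as "-2.79 from one channel into another".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .fcs_io import EventMatrix

__all__ = [
    "N_DETECTORS",
    "AUTOFLUORESCENCE",
    "SpectralSignature",
    "SignatureMatrix",
    "CompensationMatrix",
    "similarity_index",
    "similarity_matrix",
    "extract_autofluorescence",
    "unmix",
    "apply_compensation",
]

#: Detector count of the four-laser instrument model.
N_DETECTORS = 48

#: Reserved channel name for the autofluorescence endmember.
AUTOFLUORESCENCE = "AF"


@dataclass(frozen=True)
class SpectralSignature:
    """A fluorophore's normalized emission profile across detectors.

    The profile is stored normalized to unit Euclidean norm; it must be
    non-negative and not identically zero.
    """

    fluorophore: str
    profile: np.ndarray

    def __post_init__(self) -> None:
        prof = np.asarray(self.profile, dtype=float)
        if prof.ndim != 1:
            raise ValueError("profile must be a 1-D vector over detectors")
        if np.any(prof < 0):
            raise ValueError(f"{self.fluorophore}: profile must be non-negative")
        norm = float(np.linalg.norm(prof))
        if norm == 0:
            raise ValueError(f"{self.fluorophore}: profile is all zero")
        object.__setattr__(self, "profile", prof / norm)

    @property
    def n_detectors(self) -> int:
        return self.profile.shape[0]


@dataclass
class SignatureMatrix:
    """Ordered collection of signatures, optionally with autofluorescence.

    Provides the mixing matrix M (detectors x fluorophores) used by
    :func:`unmix`; when ``autofluorescence`` is set it is appended as the last
    column so intrinsic cell fluorescence is estimated alongside the markers.
    """

    signatures: list[SpectralSignature]
    autofluorescence: Optional[SpectralSignature] = None

    def __post_init__(self) -> None:
        self.signatures = list(self.signatures)
        if not self.signatures:
            raise ValueError("at least one signature required")
        counts = {s.n_detectors for s in self.signatures}
        if self.autofluorescence is not None:
            counts.add(self.autofluorescence.n_detectors)
        if len(counts) != 1:
            raise ValueError(f"signatures disagree on detector count: {sorted(counts)}")
        names = [s.fluorophore for s in self.signatures]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate fluorophore names: {dupes}")

    @property
    def n_detectors(self) -> int:
        return self.signatures[0].n_detectors

    @property
    def fluorophores(self) -> list[str]:
        return [s.fluorophore for s in self.signatures]

    def column_names(self) -> list[str]:
        names = self.fluorophores
        if self.autofluorescence is not None:
            names = names + [self.autofluorescence.fluorophore]
        return names

    def mixing_matrix(self) -> np.ndarray:
        """M with one column per endmember (autofluorescence last)."""
        cols = [s.profile for s in self.signatures]
        if self.autofluorescence is not None:
            cols.append(self.autofluorescence.profile)
        return np.column_stack(cols)

    def with_autofluorescence(self, af: SpectralSignature) -> "SignatureMatrix":
        return SignatureMatrix(signatures=self.signatures, autofluorescence=af)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignatureMatrix":
        """Load a signature library (rows = fluorophores, columns = detectors).

        A row named ``AF`` (case-insensitive) is treated as the
        autofluorescence endmember.
        """
        df = pd.read_csv(path, index_col=0)
        af = None
        sigs = []
        for name, row in df.iterrows():
            sig = SpectralSignature(str(name), row.to_numpy(dtype=float))
            if str(name).upper() == AUTOFLUORESCENCE:
                af = sig
            else:
                sigs.append(sig)
        return cls(signatures=sigs, autofluorescence=af)

    def to_csv(self, path: str | Path) -> Path:
        rows = {s.fluorophore: s.profile for s in self.signatures}
        if self.autofluorescence is not None:
            rows[self.autofluorescence.fluorophore] = self.autofluorescence.profile
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = [f"D{i}" for i in range(self.n_detectors)]
        df.to_csv(path, float_format="%.8g")
        return Path(path)


def similarity_index(a: SpectralSignature, b: SpectralSignature) -> float:
    """Cosine similarity of two unit-norm spectral profiles.

    Symmetric; 1 for identical spectra, 0 for disjoint detector support.
    """
    if a.n_detectors != b.n_detectors:
        raise ValueError(
            f"detector count mismatch: {a.fluorophore} has {a.n_detectors}, "
            f"{b.fluorophore} has {b.n_detectors}"
        )
    return float(np.clip(a.profile @ b.profile, 0.0, 1.0))


def similarity_matrix(sigs: SignatureMatrix) -> pd.DataFrame:
    """Symmetric pairwise similarity-index matrix with unit diagonal."""
    if len(sigs.signatures) < 2:
        raise ValueError("need at least 2 signatures for a similarity matrix")
    profiles = np.stack([s.profile for s in sigs.signatures])
    gram = np.clip(profiles @ profiles.T, 0.0, 1.0)
    np.fill_diagonal(gram, 1.0)
    names = sigs.fluorophores
    return pd.DataFrame(gram, index=names, columns=names)


def extract_autofluorescence(unlabeled: EventMatrix, min_events: int = 50) -> SpectralSignature:
    """Estimate the autofluorescence endmember from an unlabeled control.

    Per-detector median of the control events, normalized.  The median is
    robust to the debris and doublet outliers typical of real controls.
    """
    detectors = unlabeled.channels_of_kind("detector") or unlabeled.channel_names
    values = unlabeled.select_channels(detectors).values
    if values.shape[0] == 0:
        raise ValueError("empty unlabeled control; cannot extract autofluorescence")
    if values.shape[0] < min_events:
        warnings.warn(
            f"only {values.shape[0]} unlabeled events (<{min_events}); "
            "autofluorescence estimate may be unstable",
            stacklevel=2,
        )
    profile = np.median(values, axis=0)
    profile = np.clip(profile, 0.0, None)
    return SpectralSignature(AUTOFLUORESCENCE, profile)


def unmix(
    raw: EventMatrix,
    sigs: SignatureMatrix,
    markers: Optional[Sequence[str]] = None,
    keep_autofluorescence: bool = True,
    rank_tol: float = 1e-10,
) -> EventMatrix:
    """Ordinary-least-squares unmixing of detector-space events.

    Per event, solves ``min_a ||M a - y||^2`` over all endmembers (including
    the autofluorescence column when present).  Output columns are named by
    ``markers`` when given (one per fluorophore), otherwise by fluorophore.
    Scatter/derived columns of the input are carried through unchanged.

    Raises ``ValueError`` citing the most-collinear signature pair when M is
    rank deficient.
    """
    detector_cols = raw.channels_of_kind("detector")
    if not detector_cols:
        detector_cols = raw.channel_names
    if len(detector_cols) != sigs.n_detectors:
        raise ValueError(
            f"event matrix has {len(detector_cols)} detector channels but "
            f"signatures have {sigs.n_detectors}"
        )
    M = sigs.mixing_matrix()
    rank = np.linalg.matrix_rank(M, tol=rank_tol * np.linalg.norm(M))
    if rank < M.shape[1]:
        sim = np.abs(M.T @ M)
        np.fill_diagonal(sim, 0.0)
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        names = sigs.column_names()
        raise ValueError(
            f"signature matrix is rank deficient (rank {rank} < {M.shape[1]}); "
            f"most collinear pair: {names[i]!r} vs {names[j]!r} "
            f"(similarity {sim[i, j]:.6f})"
        )

    Y = raw.select_channels(detector_cols).values
    abundances, *_ = np.linalg.lstsq(M, Y.T, rcond=None)
    A = abundances.T

    out_names = sigs.column_names()
    if markers is not None:
        markers = list(markers)
        if len(markers) != len(sigs.signatures):
            raise ValueError("one marker name required per fluorophore signature")
        out_names = markers + out_names[len(markers):]
    kinds = ["marker"] * len(sigs.signatures)
    if sigs.autofluorescence is not None:
        kinds.append("derived")

    if not keep_autofluorescence and sigs.autofluorescence is not None:
        A = A[:, : len(sigs.signatures)]
        out_names = out_names[: len(sigs.signatures)]
        kinds = kinds[: len(sigs.signatures)]

    passthrough = [
        (n, k)
        for n, k in zip(raw.channel_names, raw.channel_kinds)
        if k in ("scatter", "derived") and n not in detector_cols
    ]
    if passthrough:
        extra = raw.select_channels([n for n, _ in passthrough]).values
        A = np.hstack([A, extra])
        out_names = out_names + [n for n, _ in passthrough]
        kinds = kinds + [k for _, k in passthrough]

    return EventMatrix(
        values=A,
        channel_names=out_names,
        channel_kinds=kinds,
        sample_id=raw.sample_id,
        batch_id=raw.batch_id,
        truth_labels=raw.truth_labels,
        metadata=dict(raw.metadata),
    )


@dataclass
class CompensationMatrix:
    """Percent-spillover coefficients over unmixed channels (diagonal 100).

    ``coefficients[i, j]`` is the percentage of channel ``i``'s signal that
    leaks into channel ``j``.  Compensation applies the inverse of
    ``coefficients / 100`` to the event matrix, so an identity matrix leaves
    values untouched.
    """

    channels: list[str]
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n = len(self.channels)
        if self.coefficients.shape != (n, n):
            raise ValueError(f"coefficients must be {n}x{n} over {self.channels}")
        if not np.allclose(np.diag(self.coefficients), 100.0):
            raise ValueError("diagonal entries must all be 100 (percent convention)")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("coefficients must be finite")

    @classmethod
    def identity(cls, channels: Sequence[str]) -> "CompensationMatrix":
        return cls(list(channels), 100.0 * np.eye(len(channels)))

    @classmethod
    def from_spillovers(
        cls, channels: Sequence[str], spills: Iterable[tuple[str, str, float]]
    ) -> "CompensationMatrix":
        """Build from sparse ``(source, target, percent)`` entries.

        E.g. ``("BYG575", "BYG710", -2.79)`` encodes a -2.79 correction from
        the first channel into the second.
        """
        comp = cls.identity(channels)
        idx = {c: i for i, c in enumerate(comp.channels)}
        for src, dst, pct in spills:
            comp.coefficients[idx[src], idx[dst]] = pct
        return comp


def apply_compensation(unmixed: EventMatrix, comp: CompensationMatrix) -> EventMatrix:
    """Apply percent-spillover compensation to unmixed events.

    Computes ``compensated = values @ inv(C/100)`` over the compensated
    channels; channels not named in the matrix pass through unchanged.
    """
    missing = [c for c in comp.channels if c not in unmixed.channel_names]
    if missing:
        raise ValueError(f"compensation channels absent from events: {missing}")
    C = comp.coefficients / 100.0
    if abs(np.linalg.det(C)) < 1e-12:
        raise ValueError("compensation matrix is singular")
    inv = np.linalg.inv(C)
    idx = [unmixed.index_of(c) for c in comp.channels]
    out = unmixed.values.copy()
    out[:, idx] = unmixed.values[:, idx] @ inv
    result = EventMatrix(
        values=out,
        channel_names=list(unmixed.channel_names),
        channel_kinds=list(unmixed.channel_kinds),
        sample_id=unmixed.sample_id,
        batch_id=unmixed.batch_id,
        truth_labels=unmixed.truth_labels,
        metadata=dict(unmixed.metadata),
    )
    return result
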