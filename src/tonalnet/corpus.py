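"""Synthetic corpora of key-labeled monophonic melodies.

Training material for the key-identification network: isochronous sequences
of tone chromas (pitch classes 0-11, C = 0), each carrying one stable key.
The generator emulates children's-songbook melodies statistically rather than
note-for-note: tone content is drawn from a tonal profile rotated to the key's
tonic, melodies are overwhelmingly in-scale, lengths fall between 17 and 186
tones, major-key items greatly outnumber minor-key items, and the corpus is
closed under transposition to all 12 keys of a mode so that no key within a
mode is easier to learn than another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.stats import pearsonr

N_CHROMAS = 12
MIN_TONES = 17
MAX_TONES = 186

PITCH_NAMES = ("C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B")

#: pitch classes of the major scale, relative to the tonic (degree 0)
MAJOR_SCALE = frozenset({0, 2, 4, 5, 7, 9, 11})
#: natural minor plus the raised leading tone (common-practice harmonic minor)
MINOR_SCALE = frozenset({0, 2, 3, 5, 7, 8, 10, 11})

#: tonic-triad degrees used to anchor the first and last tone of a melody
TONIC_TRIAD_MAJOR = (0, 4, 7)
TONIC_TRIAD_MINOR = (0, 3, 7)


class Mode(str, Enum):
    """Major or minor mode of a key."""

    MAJOR = "major"
    MINOR = "minor"

    @property
    def scale(self) -> frozenset[int]:
        """In-scale degrees (tonic-relative pitch classes) of the mode."""
        return MAJOR_SCALE if self is Mode.MAJOR else MINOR_SCALE


@dataclass(frozen=True)
class KeyLabel:
    """One of the 24 Western keys: a tonic pitch class plus a mode.

    Keys map onto the network's 24 output units through :attr:`index`:
    major keys occupy indices 0-11 (by tonic), minor keys 12-23.
    """

    tonic: int
    mode: Mode

    def __post_init__(self) -> None:
        if not 0 <= int(self.tonic) <= 11:
            raise ValueError(f"tonic must be a pitch class 0..11, got {self.tonic}")
        object.__setattr__(self, "tonic", int(self.tonic))
        object.__setattr__(self, "mode", Mode(self.mode))

    @property
    def index(self) -> int:
        return self.tonic if self.mode is Mode.MAJOR else 12 + self.tonic

    @classmethod
    def from_index(cls, index: int) -> "KeyLabel":
        if not 0 <= index <= 23:
            raise ValueError(f"key index must be 0..23, got {index}")
        return cls(index % 12, Mode.MAJOR if index < 12 else Mode.MINOR)

    def transpose(self, semitones: int) -> "KeyLabel":
        return KeyLabel((self.tonic + semitones) % 12, self.mode)

    def __str__(self) -> str:
        return f"{PITCH_NAMES[self.tonic]} {self.mode.value}"


@dataclass(frozen=True)
class Melody:
    """A monophonic, isochronous tone-chroma sequence with one stable key."""

    id: str
    chromas: tuple[int, ...]
    key: KeyLabel

    def __post_init__(self) -> None:
        chromas = tuple(int(c) for c in self.chromas)
        if not 1 <= len(chromas) <= MAX_TONES:
            raise ValueError(
                f"melody length must be 1..{MAX_TONES}, got {len(chromas)}"
            )
        if any(not 0 <= c <= 11 for c in chromas):
            raise ValueError("chromas must be pitch classes 0..11")
        object.__setattr__(self, "chromas", chromas)

    @property
    def length(self) -> int:
        return len(self.chromas)


# Probe-tone tonal hierarchies (Krumhansl-Kessler listener ratings); used only
# as relative weights for the default scale-degree sampling profiles.
_TONAL_HIERARCHY_MAJOR = np.array(
    [6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66, 2.29, 2.88]
)
_TONAL_HIERARCHY_MINOR = np.array(
    [6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75, 3.98, 2.69, 3.34, 3.17]
)


def default_profile(mode: Mode, out_of_scale_mass: float = 0.02) -> np.ndarray:
    """Default tonic-relative sampling profile for a mode.

    In-scale degrees receive weight proportional to the Krumhansl-Kessler
    tonal hierarchy (tonic, dominant and mediant heaviest) and share
    ``1 - out_of_scale_mass`` of the probability; the remaining mass is spread
    over out-of-scale degrees, again proportionally to the hierarchy values.
    """
    mode = Mode(mode)
    ratings = _TONAL_HIERARCHY_MAJOR if mode is Mode.MAJOR else _TONAL_HIERARCHY_MINOR
    in_scale = np.array([d in mode.scale for d in range(12)])
    profile = np.zeros(12)
    profile[in_scale] = ratings[in_scale] / ratings[in_scale].sum() * (1.0 - out_of_scale_mass)
    profile[~in_scale] = ratings[~in_scale] / ratings[~in_scale].sum() * out_of_scale_mass
    return profile


class EmptyCorpusError(ValueError):
    """Raised when an operation requires at least one melody."""


def _validate_profile(profile: np.ndarray, name: str = "profile") -> np.ndarray:
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (12,):
        raise ValueError(f"{name} must have length 12")
    if np.any(profile < 0):
        raise ValueError(f"{name} must be non-negative")
    if abs(profile.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {profile.sum()!r})")
    return profile


@dataclass(eq=False)
class CorpusSpec:
    """Parameters of a synthetic training corpus.

    Defaults reproduce the make-up of the songbook training set emulated
    here: 315 major-key and 41 minor-key base melodies of 17-186 tones, with
    at most ``out_of_scale_rate`` out-of-scale tones per melody.
    """

    n_major: int = 315
    n_minor: int = 41
    length_min: int = MIN_TONES
    length_max: int = MAX_TONES
    profile_major: np.ndarray = field(default_factory=lambda: default_profile(Mode.MAJOR))
    profile_minor: np.ndarray = field(default_factory=lambda: default_profile(Mode.MINOR))
    out_of_scale_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_major < 0 or self.n_minor < 0:
            raise ValueError("melody counts must be non-negative")
        if not MIN_TONES <= self.length_min <= self.length_max <= MAX_TONES:
            raise ValueError(
                f"lengths must satisfy {MIN_TONES} <= length_min <= length_max <= {MAX_TONES}"
            )
        if not 0.0 <= self.out_of_scale_rate <= 1.0:
            raise ValueError("out_of_scale_rate must lie in [0, 1]")
        self.profile_major = _validate_profile(self.profile_major, "profile_major")
        self.profile_minor = _validate_profile(self.profile_minor, "profile_minor")
        for mode, profile in ((Mode.MAJOR, self.profile_major), (Mode.MINOR, self.profile_minor)):
            oos = [d for d in range(12) if d not in mode.scale]
            if profile[oos].sum() > self.out_of_scale_rate + 1e-12:
                raise ValueError(
                    f"{mode.value} profile puts more than out_of_scale_rate mass "
                    "on out-of-scale degrees"
                )

    def profile(self, mode: Mode) -> np.ndarray:
        return self.profile_major if Mode(mode) is Mode.MAJOR else self.profile_minor


@dataclass(eq=False)
class Corpus:
    """A list of key-labeled melodies, optionally closed under transposition."""

    melodies: list[Melody]
    spec: CorpusSpec | None = None
    augmented: bool = False

    def __len__(self) -> int:
        return len(self.melodies)

    def __iter__(self) -> Iterator[Melody]:
        return iter(self.melodies)


def generate_melody(
    key: KeyLabel,
    length: int,
    profile: np.ndarray,
    rng: np.random.Generator,
    *,
    out_of_scale_rate: float = 0.05,
    melody_id: str | None = None,
) -> Melody:
    """Sample one melody in ``key`` from a tonic-relative degree profile.

    The first and last tone are anchored on the tonic triad (degrees 0, 4, 7
    in major; 0, 3, 7 in minor, drawn with the profile's relative weights, so
    the tonic itself is likeliest) — melodies open and close on a stable
    chord tone, giving each a single clear tonal center without making the
    opening tone a deterministic cue to the key. Interior tones are drawn
    i.i.d. from ``profile`` rotated to the key. At most
    ``floor(out_of_scale_rate * length)`` out-of-scale tones are admitted:
    any excess draws are resampled from the in-scale portion of the profile.
    """
    if not MIN_TONES <= length <= MAX_TONES:
        raise ValueError(f"corpus melodies must have {MIN_TONES}..{MAX_TONES} tones, got {length}")
    profile = _validate_profile(profile)
    scale = key.mode.scale
    anchors = TONIC_TRIAD_MAJOR if key.mode is Mode.MAJOR else TONIC_TRIAD_MINOR
    anchor_w = profile[list(anchors)]
    anchor_w = anchor_w / anchor_w.sum() if anchor_w.sum() > 0 else None
    degrees = np.empty(length, dtype=np.int64)
    degrees[0] = rng.choice(anchors, p=anchor_w)
    degrees[-1] = rng.choice(anchors, p=anchor_w)
    degrees[1:-1] = rng.choice(12, size=length - 2, p=profile / profile.sum())

    in_scale_mask = np.array([d in scale for d in range(12)])
    oos_positions = np.flatnonzero(~in_scale_mask[degrees])
    cap = int(np.floor(out_of_scale_rate * length))
    if len(oos_positions) > cap:
        excess = rng.choice(oos_positions, size=len(oos_positions) - cap, replace=False)
        in_profile = np.where(in_scale_mask, profile, 0.0)
        in_profile /= in_profile.sum()
        degrees[np.sort(excess)] = rng.choice(12, size=len(excess), p=in_profile)

    chromas = tuple(int((d + key.tonic) % 12) for d in degrees)
    if melody_id is None:
        melody_id = f"{PITCH_NAMES[key.tonic]}{key.mode.value[:3]}-L{length}"
    return Melody(melody_id, chromas, key)


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Generate a base (untransposed) corpus per ``spec``, reproducibly.

    All major-key melodies are generated in C major and all minor-key
    melodies in A minor; transposition augmentation makes the base-key
    choice immaterial. Lengths are sampled uniformly on
    ``[length_min, length_max]``.
    """
    if spec.n_major + spec.n_minor == 0:
        raise EmptyCorpusError("corpus spec requests zero melodies")
    rng = np.random.default_rng(spec.seed)
    melodies: list[Melody] = []
    plans = [
        (Mode.MAJOR, KeyLabel(0, Mode.MAJOR), spec.n_major, "maj"),
        (Mode.MINOR, KeyLabel(9, Mode.MINOR), spec.n_minor, "min"),
    ]
    for mode, key, count, tag in plans:
        lengths = rng.integers(spec.length_min, spec.length_max + 1, size=count)
        for i, length in enumerate(lengths):
            melodies.append(
                generate_melody(
                    key,
                    int(length),
                    spec.profile(mode),
                    rng,
                    out_of_scale_rate=spec.out_of_scale_rate,
                    melody_id=f"{tag}{i:03d}",
                )
            )
    return Corpus(melodies, spec=spec, augmented=False)


def transpose_melody(melody: Melody, semitones: int) -> Melody:
    """Shift every chroma (and the key's tonic) by ``semitones`` mod 12."""
    semitones = int(semitones) % 12
    if semitones == 0:
        return melody
    return Melody(
        melody.id,
        tuple((c + semitones) % 12 for c in melody.chromas),
        melody.key.transpose(semitones),
    )


def augment_by_transposition(corpus: Corpus) -> Corpus:
    """Replace every melody by its 12 same-mode transpositions.

    With the default corpus make-up (315 major + 41 minor base melodies) this
    yields the 4,272 training items presented per epoch.
    """
    if corpus.augmented:
        raise ValueError("corpus is already transposition-augmented")
    if len(corpus) == 0:
        raise EmptyCorpusError("cannot augment an empty corpus")
    melodies = []
    for m in corpus:
        for s in range(12):
            t = transpose_melody(m, s)
            melodies.append(Melody(f"{m.id}.T{s:02d}", t.chromas, t.key))
    return Corpus(melodies, spec=corpus.spec, augmented=True)


def chroma_distribution(corpus: Corpus, mode: Mode) -> np.ndarray:
    """Relative frequency of tonic-relative scale degrees, pooled over a mode."""
    mode = Mode(mode)
    counts = np.zeros(12)
    found = False
    for m in corpus:
        if m.key.mode is mode:
            found = True
            degrees = (np.asarray(m.chromas) - m.key.tonic) % 12
            np.add.at(counts, degrees, 1.0)
    if not found:
        raise EmptyCorpusError(f"corpus contains no {mode.value}-key melodies")
    return counts / counts.sum()


def profile_correlation(distribution: Sequence[float], reference: Sequence[float]) -> float:
    """Pearson correlation between two 12-degree frequency profiles.

    Validation hook for comparing a generated corpus against a published
    tone-distribution profile.
    """
    d = np.asarray(distribution, dtype=float)
    r = np.asarray(reference, dtype=float)
    if d.shape != (12,) or r.shape != (12,):
        raise ValueError("profiles must have length 12")
    if np.ptp(d) == 0 or np.ptp(r) == 0:
        raise ValueError("correlation is undefined for a constant profile")
    return float(pearsonr(d, r).statistic)


# ---------------------------------------------------------------------------
# JSON melody interchange
# ---------------------------------------------------------------------------

def melody_to_dict(m: Melody) -> dict:
    return {
        "id": m.id,
        "key": {"tonic": m.key.tonic, "mode": m.key.mode.value},
        "chromas": list(m.chromas),
    }


def melody_from_dict(d: dict) -> Melody:
    key = KeyLabel(d["key"]["tonic"], Mode(d["key"]["mode"]))
    return Melody(d["id"], tuple(d["chromas"]), key)


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSON-Lines, one melody object per line."""
    with open(path, "w") as fh:
        for m in corpus:
            fh.write(json.dumps(melody_to_dict(m)) + "\n")


def load_corpus(path: str | Path, *, augmented: bool = False) -> Corpus:
    melodies = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                melodies.append(melody_from_dict(json.loads(line)))
    return Corpus(melodies, spec=None, augmented=augmented)
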