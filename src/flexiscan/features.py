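"""Per-intron sequence features.

GC fraction, splice-site dinucleotides and U2/U12/non-canonical class,
branch-point position-weight-matrix (PWM) scan within the 3'-terminal window,
position-frequency consensus tables, minimum free energy (MFE) via a
pluggable folding backend, and mean per-base conservation.

PWMs (U12-type 5' splice site, U2- and U12-type branch points) ship as
editable TSV files under ``flexiscan/pwm_data/``, seeded from the published
consensus frequencies for the major and minor spliceosomal intron classes.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from flexiscan.annotations import IntronCatalog, IntronRecord, _fetch_seq

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def gc_fraction(sequence: str) -> Optional[float]:
    """(#G + #C) / (#A + #C + #G + #T); N bases excluded from the denominator.

    Returns None (with a warning) for an all-N sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper().replace("U", "T")
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        warnings.warn("all-N sequence; GC fraction undefined")
        return None
    return gc / denom


# --------------------------------------------------------------------- PWMs


@dataclass
class PWM:
    """Per-position log-odds (bits) nucleotide matrix over a uniform background."""

    name: str
    matrix: np.ndarray  # shape (length, 4), order ACGT
    score_threshold: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM entries must be finite")
        if not np.isfinite(self.score_threshold):
            raise ValueError("threshold must be finite")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def score(self, window: str) -> float:
        """Log-odds score of one window (N scores 0 at its position)."""
        if len(window) != len(self):
            raise ValueError("window length mismatch")
        total = 0.0
        for i, b in enumerate(window.upper().replace("U", "T")):
            j = _BASE_IDX.get(b)
            if j is not None:
                total += self.matrix[i, j]
        return total

    @classmethod
    def from_frequencies(
        cls,
        name: str,
        freqs: np.ndarray,
        pseudocount: float = 0.0,
        threshold_frac: float = 0.6,
    ) -> "PWM":
        """Build from per-position frequencies; log2 odds vs uniform 0.25.

        The default threshold is ``threshold_frac`` of the consensus
        sequence's own score.
        """
        f = np.asarray(freqs, dtype=float) + pseudocount
        f = f / f.sum(axis=1, keepdims=True)
        mat = np.log2(np.maximum(f, 1e-9) / 0.25)
        consensus_score = mat.max(axis=1).sum()
        return cls(name=name, matrix=mat, score_threshold=threshold_frac * consensus_score)

    @classmethod
    def from_tsv(cls, path, threshold_frac: float = 0.6) -> "PWM":
        """Read a frequency TSV (columns A C G T, one row per position)."""
        df = pd.read_csv(path, sep="\t")
        return cls.from_frequencies(
            Path(str(path)).stem, df[list(BASES)].to_numpy(), threshold_frac=threshold_frac
        )


def load_builtin_pwm(name: str, threshold_frac: float = 0.6) -> PWM:
    """Load one of the shipped PWMs: 'u12_5ss', 'u2_bp', 'u12_bp'."""
    ref = resources.files("flexiscan") / "pwm_data" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        pwm = PWM.from_tsv(path, threshold_frac=threshold_frac)
    pwm.name = name
    return pwm


# --------------------------------------------------------- splice-site class

SPLICE_CLASSES = ("U2_GU_AG", "U2_GC_AG", "U12_GU_AG", "U12_AU_AC", "noncanonical")


def classify_splice_type(sequence: str, u12_5ss_pwm: Optional[PWM] = None) -> str:
    """Assign a splice-site class from the intron's terminal dinucleotides.

    AU-AC ends are minor-spliceosome (U12) introns; GU-AG ends are minor-type
    only when the first 12 nt match the U12 5' splice-site consensus (PWM
    score >= threshold), otherwise major-type (U2); GC-AG is the U2 variant;
    anything else is non-canonical.  Sequences are read as RNA (T == U).
    """
    if len(sequence) < 4:
        raise ValueError("sequence shorter than 4 nt")
    s = sequence.upper().replace("U", "T")
    d5, d3 = s[:2], s[-2:]
    if d5 == "AT" and d3 == "AC":
        return "U12_AU_AC"
    if d5 == "GT" and d3 == "AG":
        if u12_5ss_pwm is None:
            u12_5ss_pwm = load_builtin_pwm("u12_5ss")
        if len(s) < len(u12_5ss_pwm):
            warnings.warn("sequence shorter than U12 5'SS PWM; classified by ends only")
            return "U2_GU_AG"
        if u12_5ss_pwm.score(s[: len(u12_5ss_pwm)]) >= u12_5ss_pwm.score_threshold:
            return "U12_GU_AG"
        return "U2_GU_AG"
    if d5 == "GC" and d3 == "AG":
        return "U2_GC_AG"
    return "noncanonical"


def splice_dinucleotides(sequence: str) -> tuple[str, str]:
    s = sequence.upper().replace("T", "U")
    return s[:2], s[-2:]


# ------------------------------------------------------------- branch point


def scan_branch_point(
    sequence: str, bp_pwm: PWM, window: int = 40, exclude_3p: int = 3
) -> Optional[tuple[int, float]]:
    """Best-scoring PWM position within the last ``window`` nt of the intron,
    excluding the terminal ``exclude_3p`` nt.

    Returns ``(bp_offset, bp_score)`` where ``bp_offset`` is the (negative)
    offset of the motif start from the intron 3' end, or None when no
    position reaches the PWM threshold.  Ties resolve to the position closest
    to the 3' end.
    """
    s = sequence.upper().replace("U", "T")
    if window > len(s):
        raise ValueError("window exceeds sequence length")
    if len(bp_pwm) > window:
        raise ValueError("PWM longer than search window")
    lo = len(s) - window
    hi = len(s) - exclude_3p - len(bp_pwm)
    if hi < lo:
        return None
    best: Optional[tuple[int, float]] = None
    for pos in range(lo, hi + 1):
        sc = bp_pwm.score(s[pos : pos + len(bp_pwm)])
        if best is None or sc > best[1] or (sc == best[1] and pos > best[0]):
            best = (pos, sc)
    if best is None or best[1] < bp_pwm.score_threshold:
        return None
    return best[0] - len(s), best[1]


def consensus_frequency_table(
    sequences: Sequence[str],
    anchor: str = "5ss",
    span: int = 8,
    bp_pwm: Optional[PWM] = None,
    bp_window: int = 40,
) -> pd.DataFrame:
    """Per-position nucleotide frequency matrix (columns sum to 1).

    ``anchor`` is one of '5ss' (first ``span`` nt), '3ss' (last ``span`` nt),
    or 'bp' (aligned at each sequence's branch-point call; sequences lacking
    a call are excluded, with the excluded count reported as a warning).
    """
    if not sequences:
        raise ValueError("no sequences")
    windows = []
    n_excluded = 0
    for seq in sequences:
        s = seq.upper().replace("U", "T")
        if anchor == "5ss":
            if len(s) < span:
                n_excluded += 1
                continue
            windows.append(s[:span])
        elif anchor == "3ss":
            if len(s) < span:
                n_excluded += 1
                continue
            windows.append(s[-span:])
        elif anchor == "bp":
            if bp_pwm is None:
                raise ValueError("bp anchor requires bp_pwm")
            hit = None
            if bp_window <= len(s):
                hit = scan_branch_point(s, bp_pwm, window=bp_window)
            if hit is None or len(s) + hit[0] + span > len(s):
                n_excluded += 1
                continue
            start = len(s) + hit[0]
            windows.append(s[start : start + span])
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
    if n_excluded:
        warnings.warn(f"{n_excluded} sequences excluded from consensus table")
    if not windows:
        raise ValueError("no usable sequences")
    counts = np.zeros((span, 4))
    denom = np.zeros(span)
    for w in windows:
        for i, b in enumerate(w):
            j = _BASE_IDX.get(b)
            if j is not None:
                counts[i, j] += 1
                denom[i] += 1
    freqs = counts / np.maximum(denom, 1)[:, None]
    df = pd.DataFrame(freqs.T, index=list("ACGU"))
    df.columns = [f"pos{i+1}" for i in range(span)]
    return df


# ------------------------------------------------------------------ folding


def _nussinov_pairs_py(enc: np.ndarray, min_loop: int) -> int:
    """Maximum number of nested Watson-Crick pairs (A=65, C=67, G=71, T=84)."""
    n = enc.size
    pairsum = {65 + 84, 67 + 71}
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            for k in range(i, j - min_loop):
                if int(enc[k]) + int(enc[j]) in pairsum:
                    left = dp[i, k - 1] if k > i else 0
                    cand = left + dp[k + 1, j - 1] + 1
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return int(dp[0, n - 1]) if n else 0


try:  # compiled DP; pure-python fallback keeps the package importable
    from numba import njit

    @njit(cache=False)
    def _nussinov_pairs_nb(enc, min_loop):
        n = enc.size
        dp = np.zeros((n, n), dtype=np.int32)
        for span in range(min_loop + 1, n):
            for i in range(n - span):
                j = i + span
                best = dp[i, j - 1]
                cj = enc[j]
                for k in range(i, j - min_loop):
                    ck = enc[k]
                    ok = (ck == 65 and cj == 84) or (ck == 84 and cj == 65) or (
                        ck == 71 and cj == 67
                    ) or (ck == 67 and cj == 71)
                    if ok:
                        left = dp[i, k - 1] if k > i else 0
                        cand = left + dp[k + 1, j - 1] + 1
                        if cand > best:
                            best = cand
                dp[i, j] = best
        return dp[0, n - 1] if n > 0 else 0

    def _nussinov_pairs(enc: np.ndarray, min_loop: int) -> int:
        return int(_nussinov_pairs_nb(enc, min_loop))

except ImportError:  # pragma: no cover
    _nussinov_pairs = _nussinov_pairs_py


class StubFolder:
    """Base-pair-maximization folding stub (non-thermodynamic).

    Nussinov-style dynamic program over Watson-Crick pairs (A:U, G:C) with a
    fixed pseudo-energy per pair and a minimum hairpin loop of 3 unpaired
    bases.  Deterministic and dependency-free; scores are NOT free energies,
    only a structure-capacity proxy used for testing and synthetic analyses.
    """

    name = "stub"
    PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

    def __init__(self, energy_per_pair: float = -1.0, min_loop: int = 3):
        self.energy_per_pair = energy_per_pair
        self.min_loop = min_loop

    def fold_mfe(self, sequence: str) -> float:
        s = sequence.upper().replace("U", "T")
        n = len(s)
        if n == 0:
            return 0.0
        enc = np.frombuffer(s.encode(), dtype=np.uint8)
        return float(_nussinov_pairs(enc, self.min_loop)) * self.energy_per_pair


class RnaFoldBackend:
    """Adapter to the ViennaRNA ``RNAfold`` command-line folder."""

    name = "rnafold"

    def __init__(self, executable: str = "RNAfold"):
        self.executable = executable

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def fold_mfe(self, sequence: str) -> Optional[float]:
        if not self.available():
            warnings.warn("RNAfold not on PATH; MFE null")
            return None
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=sequence.upper().replace("T", "U") + "\n",
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            warnings.warn(f"RNAfold failed: {proc.stderr.strip()}")
            return None
        # last line: "(((...))) ( -3.40)"
        last = proc.stdout.strip().splitlines()[-1]
        mfe = float(last.rsplit("(", 1)[1].rstrip(")").strip())
        return min(mfe, 0.0)


def fold_mfe(sequence: str, folder=None) -> Optional[float]:
    """Minimum free energy (kcal/mol, <= 0) under the given backend.

    Defaults to the built-in base-pair-maximization stub; returns None when
    an external backend is unavailable.
    """
    folder = folder or StubFolder()
    mfe = folder.fold_mfe(sequence)
    return None if mfe is None else min(mfe, 0.0)


# ------------------------------------------------------------- conservation


class ConservationTrack:
    """Per-base conservation scores loaded from a bedGraph."""

    def __init__(self, intervals: dict[str, list[tuple[int, int, float]]]):
        self._iv = {c: sorted(v) for c, v in intervals.items()}
        self._starts = {
            c: np.array([s for s, _, _ in v]) for c, v in self._iv.items()
        }

    @classmethod
    def from_bedgraph(cls, path: Union[str, Path]) -> "ConservationTrack":
        intervals: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, value = line.split()[:4]
                intervals.setdefault(chrom, []).append(
                    (int(start), int(end), float(value))
                )
        return cls(intervals)

    def chroms(self) -> set:
        return set(self._iv)

    def sum_over(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base scores over [start, end); absent bases contribute 0."""
        if chrom not in self._iv:
            raise KeyError(chrom)
        total = 0.0
        ivs = self._iv[chrom]
        idx = int(np.searchsorted(self._starts[chrom], start, side="right")) - 1
        idx = max(idx, 0)
        for s, e, v in ivs[idx:]:
            if s >= end:
                break
            ov = min(e, end) - max(s, start)
            if ov > 0:
                total += ov * v
        return total


def phastcons_mean(intron: IntronRecord, track: ConservationTrack) -> Optional[float]:
    """Arithmetic mean conservation over all intron bases; bases absent from
    the track count as 0.  None (with a warning) when the chromosome is
    absent from the track entirely.
    """
    if intron.chrom not in track.chroms():
        warnings.warn(f"chromosome {intron.chrom} absent from conservation track")
        return None
    return track.sum_over(intron.chrom, intron.start, intron.end) / intron.length


# ------------------------------------------------------------- feature table


def compute_features(
    catalog: IntronCatalog,
    genome,
    track: Optional[ConservationTrack] = None,
    folder=None,
    u12_5ss_pwm: Optional[PWM] = None,
    u2_bp_pwm: Optional[PWM] = None,
    bp_window: int = 40,
    mfe_max_len: Optional[int] = 400,
) -> pd.DataFrame:
    """Feature table keyed by intron_id for every catalog intron.

    MFE is computed for sequences up to ``mfe_max_len`` nt (None = no limit);
    longer introns get a null MFE — secondary-structure stability is a
    short-intron characterization and the cubic-time fold dominates runtime
    otherwise.
    """
    u12_5ss_pwm = u12_5ss_pwm or load_builtin_pwm("u12_5ss")
    u2_bp_pwm = u2_bp_pwm or load_builtin_pwm("u2_bp")
    folder = folder or StubFolder()
    rows = []
    for intron in catalog:
        seq = _fetch_seq(genome, intron)
        d5, d3 = splice_dinucleotides(seq)
        bp = (
            scan_branch_point(seq, u2_bp_pwm, window=min(bp_window, len(seq)))
            if len(seq) >= len(u2_bp_pwm) + 3
            else None
        )
        rows.append(
            {
                "intron_id": intron.intron_id,
                "length": intron.length,
                "gc_fraction": gc_fraction(seq),
                "mfe": (
                    fold_mfe(seq, folder)
                    if mfe_max_len is None or len(seq) <= mfe_max_len
                    else None
                ),
                "splice_class": classify_splice_type(seq, u12_5ss_pwm),
                "dinuc_5": d5,
                "dinuc_3": d3,
                "bp_offset": bp[0] if bp else None,
                "bp_score": bp[1] if bp else None,
                "phastcons_mean": (
                    phastcons_mean(intron, track) if track is not None else None
                ),
            }
        )
    return pd.DataFrame(rows)
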