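"""Per-cycle base-call trimming of FASTQ reads.

For a read set, the number of base calls observed at each read cycle j
(position within the read) is f_j.  Cycles whose call count deviates from
the mean of the f vector by more than ``k_sd`` population standard
deviations are anomalous — typically the ragged tail cycles of a
variable-length read set — and are removed from every read.  Reads that
fall below the minimum length after column removal are dropped, mirroring
the minimum-length filter applied upstream of this step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

DEFAULT_MIN_LEN = 45


@dataclass
class CycleCallProfile:
    """Per-cycle base-call counts with their mean and population SD."""

    calls: np.ndarray  # f_j for cycles 1..max read length
    mean: float
    sd: float

    @property
    def n_cycles(self) -> int:
        return len(self.calls)


def cycle_call_profile(reads: list[SeqRecord]) -> CycleCallProfile:
    if not reads:
        raise InputError("empty read set")
    lengths = np.array([len(r.seq) for r in reads])
    max_len = int(lengths.max())
    # f_j = number of reads long enough to have a call at cycle j
    calls = (lengths[:, None] >= np.arange(1, max_len + 1)[None, :]).sum(axis=0)
    calls = calls.astype(float)
    return CycleCallProfile(calls=calls, mean=float(calls.mean()), sd=float(calls.std()))


def flag_cycles(profile: CycleCallProfile, k_sd: float = 2.0) -> set[int]:
    """1-based cycles whose call count deviates from the mean by > k_sd SDs."""
    if k_sd <= 0:
        raise InputError("k_sd must be positive")
    if math.isinf(k_sd) or profile.sd == 0.0:
        return set()
    dev = np.abs(profile.calls - profile.mean)
    return set(int(j) for j in np.nonzero(dev > k_sd * profile.sd)[0] + 1)


def per_cycle_call_trim(
    reads: list[SeqRecord], k_sd: float = 2.0, min_len: int = DEFAULT_MIN_LEN
) -> tuple[list[SeqRecord], CycleCallProfile, set[int]]:
    """Remove anomalous cycle columns from every read.

    Returns the trimmed reads (those still >= ``min_len`` bases), the cycle
    profile, and the set of cut cycles (1-based).  Quality strings are cut
    in lockstep with the bases so the FASTQ stays valid.
    """
    profile = cycle_call_profile(reads)
    cut = flag_cycles(profile, k_sd)
    if not cut:
        return list(reads), profile, cut

    trimmed: list[SeqRecord] = []
    for r in reads:
        keep = [i for i in range(len(r.seq)) if (i + 1) not in cut]
        if len(keep) < min_len:
            continue
        seq = "".join(str(r.seq)[i] for i in keep)
        quals = r.letter_annotations.get("phred_quality")
        new = SeqRecord(Seq(seq), id=r.id, name=r.name, description=r.description)
        if quals is not None:
            new.letter_annotations["phred_quality"] = [quals[i] for i in keep]
        trimmed.append(new)
    return trimmed, profile, cut


def trim_fastq(
    in_path: str, out_path: str, k_sd: float = 2.0, min_len: int = DEFAULT_MIN_LEN
) -> tuple[CycleCallProfile, set[int], int]:
    """File-level wrapper; returns (profile, cut cycles, reads written)."""
    reads = list(SeqIO.parse(in_path, "fastq"))
    trimmed, profile, cut = per_cycle_call_trim(reads, k_sd=k_sd, min_len=min_len)
    SeqIO.write(trimmed, out_path, "fastq")
    return profile, cut, len(trimmed)
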