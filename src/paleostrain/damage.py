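"""Post-mortem deamination profiling and ancientness authentication.

Ancient DNA carries cytosine deamination that sequencing reads out as C->T
substitutions concentrated at the 5' ends of fragments (and, in
double-stranded libraries, G->A at 3' ends), decaying roughly exponentially
into the read. :func:`misincorporation_profile` tallies these per-position
frequencies from alignments; :func:`authenticate` applies a simple decision
rule — a terminal C->T rate that is both absolutely elevated and a multiple
of the interior baseline — standing in for visual inspection of damage
plots. The thresholds are configurable and are echoed in the report; no
community-standard numeric cutoff exists.

Reverse-strand alignments are rotated into read orientation before
tallying, so deamination is always counted as C->T at the read 5' end
regardless of mapping strand. Ambiguity codes are excluded from numerator
and denominator alike.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alignment import ReadAlignment


@dataclass
class DamageProfile:
    """Per-position terminal misincorporation frequencies.

    Positions are 1-based from each read end over ``window`` positions;
    fractions are defined (non-NaN) only where the opportunity count is
    positive. ``interior_ct_baseline`` pools C->T at positions more than
    ``window`` from both ends.
    """

    window: int
    ct_5p: np.ndarray
    ga_3p: np.ndarray
    n_obs_5p: np.ndarray
    n_obs_3p: np.ndarray
    interior_ct_baseline: float

    def to_rows(self) -> list[dict]:
        return [{"position": p + 1,
                 "ct_5p": "" if np.isnan(self.ct_5p[p]) else f"{self.ct_5p[p]:.6f}",
                 "n_obs_5p": int(self.n_obs_5p[p]),
                 "ga_3p": "" if np.isnan(self.ga_3p[p]) else f"{self.ga_3p[p]:.6f}",
                 "n_obs_3p": int(self.n_obs_3p[p])}
                for p in range(self.window)]


def misincorporation_profile(alignments: list[ReadAlignment],
                             window: int = 25) -> DamageProfile:
    """Tally C->T (5') and G->A (3') frequencies per terminal position.

    ct_5p[p] = (# reference-C opportunities at read position p read as T) /
    (# reference-C opportunities at position p), with p counted in read
    orientation; ga_3p symmetrically from the 3' end.
    """
    if window < 5:
        raise ValueError("window must be >= 5")
    ct = np.zeros(window); obs5 = np.zeros(window)
    ga = np.zeros(window); obs3 = np.zeros(window)
    int_ct = int_obs = 0
    for aln in alignments:
        if not aln.aligned_pairs:
            raise ValueError(f"alignment {aln.read_id} carries no per-base "
                             "read/reference pairing")
        pairs = list(aln.pairs_in_read_orientation())
        n = len(pairs)
        for i, (qb, rb) in enumerate(pairs):
            if rb == "C" and qb in "ACGT":
                if i < window:
                    obs5[i] += 1
                    if qb == "T":
                        ct[i] += 1
                if i >= window and (n - 1 - i) >= window:
                    int_obs += 1
                    if qb == "T":
                        int_ct += 1
            d3 = n - 1 - i
            if rb == "G" and qb in "ACGT" and d3 < window:
                obs3[d3] += 1
                if qb == "A":
                    ga[d3] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ct_f = np.where(obs5 > 0, ct / np.maximum(obs5, 1), np.nan)
        ga_f = np.where(obs3 > 0, ga / np.maximum(obs3, 1), np.nan)
    baseline = int_ct / int_obs if int_obs else float("nan")
    return DamageProfile(window, ct_f, ga_f, obs5.astype(int), obs3.astype(int),
                         baseline)


@dataclass
class AuthenticationReport:
    """Outcome of the damage-based authentication rule."""

    authentic: bool | None
    status: str  # 'ok' or 'insufficient data'
    terminal_ct: float = float("nan")
    terminal_ga: float = float("nan")
    baseline: float = float("nan")
    min_terminal_rate: float = 0.05
    min_fold_over_baseline: float = 2.0
    details: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {"authentic": self.authentic, "status": self.status,
             "terminal_ct_5p": None if np.isnan(self.terminal_ct) else self.terminal_ct,
             "terminal_ga_3p": None if np.isnan(self.terminal_ga) else self.terminal_ga,
             "interior_ct_baseline": None if np.isnan(self.baseline) else self.baseline,
             "min_terminal_rate": self.min_terminal_rate,
             "min_fold_over_baseline": self.min_fold_over_baseline}
        d.update(self.details)
        return json.dumps(d, indent=2)


def authenticate(profile: DamageProfile, min_terminal_rate: float = 0.05,
                 min_fold_over_baseline: float = 2.0) -> AuthenticationReport:
    """Decide ancient authenticity from a damage profile.

    Authentic iff ct_5p[1] >= min_terminal_rate AND ct_5p[1] >=
    min_fold_over_baseline x interior baseline, and symmetrically for
    ga_3p where 3'-end observations exist. A profile with no terminal
    C observations yields an 'insufficient data' outcome rather than a
    crash.
    """
    if profile.n_obs_5p[0] == 0:
        return AuthenticationReport(None, "insufficient data",
                                    min_terminal_rate=min_terminal_rate,
                                    min_fold_over_baseline=min_fold_over_baseline)
    ct1 = float(profile.ct_5p[0])
    base = profile.interior_ct_baseline
    fold_ok = True if np.isnan(base) else ct1 >= min_fold_over_baseline * base
    ok5 = ct1 >= min_terminal_rate and fold_ok
    ga1 = float(profile.ga_3p[0]) if profile.n_obs_3p[0] > 0 else float("nan")
    if not np.isnan(ga1):
        ok3 = (ga1 >= min_terminal_rate
               and (np.isnan(base) or ga1 >= min_fold_over_baseline * base))
    else:
        ok3 = True  # unstranded / no 3' information: 5' rule decides
    return AuthenticationReport(bool(ok5 and ok3), "ok", ct1, ga1, base,
                                min_terminal_rate, min_fold_over_baseline)
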