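"""End-member sediment mixing model.

The ratio of authigenic-clay silica to total silica expressed in a bulk
sediment (f_rw_s) mixes an authigenic and a detrital component:

    f_s = M_a * f_a + M_d * f_d,   M_a + M_d = 1

with M_a the authigenic mass fraction (authigenic SiO2 + authigenic
clays, including water-column biogenic silica), f_a and f_d the ratios
of the two components. Monte Carlo sampling of (M_a, f_a, f_d) with
uniform priors, filtered on the sediment-expressed ranges observed
before and after the extinction horizon, constrains the authigenic
ratio f_a required to produce the observed shift.

Because f_s <= max(f_a, f_d), whenever the detrital ratio cannot
exceed the lower edge of the post-extinction filter window the minimum
accepted f_a is bounded below by that edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: filter presets for the post-extinction sediment ratio
POST_RANGE_METHODS = (0.15, 0.55)   # full post-extinction range
POST_RANGE_OBSERVED = (0.2, 0.3)    # observed mineralogical estimate
PRE_RANGE = (0.0, 0.15)
F_D_RANGE = (0.0, 0.15)


def mix(m_a, f_a, f_d):
    """Sediment-expressed ratio of a two-component mixture.

    f_s = m_a*f_a + (1-m_a)*f_d; accepts scalars or arrays, all
    arguments in [0, 1].
    """
    m_a = np.asarray(m_a, dtype=float)
    f_a = np.asarray(f_a, dtype=float)
    f_d = np.asarray(f_d, dtype=float)
    for name, v in (("m_a", m_a), ("f_a", f_a), ("f_d", f_d)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = m_a * f_a + (1.0 - m_a) * f_d
    return out if out.ndim else float(out)


@dataclass
class MixingResult:
    """Raw draws and the pre/post accepted subsets."""

    draws: pd.DataFrame
    pre: pd.DataFrame
    post: pd.DataFrame
    pre_range: tuple
    post_range: tuple
    seed: int

    @property
    def n(self) -> int:
        return len(self.draws)

    @property
    def empty_pre(self) -> bool:
        return len(self.pre) == 0

    @property
    def empty_post(self) -> bool:
        return len(self.post) == 0


def sample_and_filter(
    n: int,
    f_d_range: tuple = F_D_RANGE,
    pre_range: tuple = PRE_RANGE,
    post_range: tuple = POST_RANGE_METHODS,
    seed: int = 0,
) -> MixingResult:
    """Draw mixing triples and filter on the sediment-expressed ratio.

    M_a ~ U(0,1) with M_d = 1 - M_a, f_a ~ U(0,1), f_d uniform on
    f_d_range. A draw joins the pre (resp. post) accepted set iff its
    f_s falls in pre_range (resp. post_range); the same raw draws are
    filtered against both windows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, rng_ in (("f_d_range", f_d_range), ("pre_range", pre_range),
                       ("post_range", post_range)):
        lo, hi = rng_
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"{name} must be an ordered interval within [0, 1]")
    rng = np.random.default_rng(seed)
    m_a = rng.uniform(0.0, 1.0, n)
    f_a = rng.uniform(0.0, 1.0, n)
    f_d = rng.uniform(f_d_range[0], f_d_range[1], n)
    f_s = mix(m_a, f_a, f_d)
    draws = pd.DataFrame({"m_a": m_a, "m_d": 1.0 - m_a, "f_a": f_a, "f_d": f_d, "f_s": f_s})
    pre = draws[(f_s >= pre_range[0]) & (f_s <= pre_range[1])]
    post = draws[(f_s >= post_range[0]) & (f_s <= post_range[1])]
    return MixingResult(
        draws=draws, pre=pre.reset_index(drop=True), post=post.reset_index(drop=True),
        pre_range=tuple(pre_range), post_range=tuple(post_range), seed=seed,
    )


def summarize_mixing(accepted: pd.DataFrame, bin_width: float = 0.025) -> dict:
    """Distribution summary of an accepted draw set.

    Histograms (documented fixed bin width on [0, 1]), the modal bin
    center, and percentile intervals for M_d, M_a and f_a. Entirely
    deterministic given the draws.
    """
    if len(accepted) == 0:
        raise ValueError("accepted draw set is empty")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    out: dict = {"n": int(len(accepted)), "bin_width": bin_width}
    for col in ("m_d", "m_a", "f_a"):
        x = accepted[col].to_numpy()
        counts, _ = np.histogram(x, bins=edges)
        mode_center = edges[int(np.argmax(counts))] + bin_width / 2.0
        q = np.percentile(x, [2.5, 16, 50, 84, 97.5])
        out[col] = {
            "counts": counts,
            "mode": float(mode_center),
            "min": float(x.min()),
            "max": float(x.max()),
            "p2.5": float(q[0]),
            "p16": float(q[1]),
            "median": float(q[2]),
            "p84": float(q[3]),
            "p97.5": float(q[4]),
            "mean": float(x.mean()),
        }
    return out


def conditional_acceptance(
    f_a: float,
    post_range: tuple = POST_RANGE_METHODS,
    f_d_range: tuple = F_D_RANGE,
    n: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte Carlo acceptance probability of the filter at fixed f_a.

    Samples (M_a, f_d) from their priors and reports the fraction of
    mixtures whose f_s falls inside post_range.
    """
    rng = np.random.default_rng(seed)
    m_a = rng.uniform(0.0, 1.0, n)
    f_d = rng.uniform(f_d_range[0], f_d_range[1], n)
    f_s = mix(m_a, np.full(n, float(f_a)), f_d)
    return float(np.mean((f_s >= post_range[0]) & (f_s <= post_range[1])))
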