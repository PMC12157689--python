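"""Trio phasing: Mendelian rules, then mask-and-impute for triple heterozygotes.

A child is phased into a paternal and a maternal haplotype. Sites where
father, mother and child are all heterozygous (triple-het) cannot be
resolved by Mendelian logic; they are masked, each parental haplotype is
imputed under a Li-Stephens copying model against a reference panel, and
at each masked site the haplotype with the larger imputed alt-allele
dosage receives the alt allele (1), the other the ref allele (0).

Genotype conventions: alt-allele counts in {0, 1, 2}, with -1 for missing.
Haplotype alleles are {0, 1} with -1 for missing. At a Mendelian
incompatibility the child's genotype is trusted: a heterozygous child is
masked (unresolvable), a homozygous child is phased from its own genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MENDELIAN", "UNRESOLVED", "ERROR_MASKED", "IMPUTED",
    "MISSING",
    "PhasedChild",
    "HmmParams",
    "mendelian_phase",
    "LiStephensHMM",
    "impute_dosage",
    "resolve_triple_het",
    "phasing_error_rate",
    "mendelian_error_mask",
    "build_parent_panel",
    "phase_trio_dataset",
]

MISSING = -1

# resolved_by codes
MENDELIAN = 0      # forced by Mendelian transmission (or by a homozygous child)
UNRESOLVED = 1     # triple heterozygous, awaiting imputation
ERROR_MASKED = 2   # Mendelian-incompatible with a heterozygous child
IMPUTED = 3        # filled in by dosage comparison


@dataclass
class PhasedChild:
    """Paternal/maternal haplotypes of one child plus provenance tags."""

    h_pat: np.ndarray       # int8, {0, 1, -1}
    h_mat: np.ndarray
    resolved_by: np.ndarray  # uint8 codes above
    pat_dosage: np.ndarray | None = None  # filled by imputation
    mat_dosage: np.ndarray | None = None


@dataclass
class HmmParams:
    """Li-Stephens copying model parameters.

    ``panel`` holds phased reference haplotypes (H x S, {0,1,-1}); ``rho``
    is the per-interval probability of switching template (the new template
    is uniform over the panel, including the current one); ``eps`` is the
    per-site copying-error probability. Missing panel entries emit either
    allele with probability 1/2.
    """

    panel: np.ndarray
    rho: float = 0.01
    eps: float = 0.001

    def __post_init__(self):
        self.panel = np.asarray(self.panel, dtype=np.int8)
        if self.panel.ndim != 2 or self.panel.shape[0] < 1:
            raise ValueError("panel must be a non-empty H x S array")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 < self.eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")


# ---------------------------------------------------------------------------
# Mendelian phasing via a precomputed lookup table over (gF, gM, gC)
# ---------------------------------------------------------------------------

def _alleles(g: int) -> set[int]:
    if g == MISSING:
        return {0, 1}
    return {0} if g == 0 else {1} if g == 2 else {0, 1}


def _phase_one(gf: int, gm: int, gc: int) -> tuple[int, int, int]:
    if gc == MISSING:
        return MISSING, MISSING, UNRESOLVED
    pairs = [(p, gc - p) for p in (0, 1)
             if gc - p in (0, 1) and p in _alleles(gf) and (gc - p) in _alleles(gm)]
    if gc in (0, 2):
        # homozygous child: forced regardless of parental (in)compatibility
        return gc // 2, gc // 2, MENDELIAN
    if len(pairs) == 1:
        return pairs[0][0], pairs[0][1], MENDELIAN
    if len(pairs) == 0:
        # incompatible, heterozygous child: trust the child, mask the site
        return MISSING, MISSING, ERROR_MASKED
    return MISSING, MISSING, UNRESOLVED  # triple heterozygous


_LUT = np.empty((4, 4, 4, 3), dtype=np.int8)
for _f in (-1, 0, 1, 2):
    for _m in (-1, 0, 1, 2):
        for _c in (-1, 0, 1, 2):
            _LUT[_f, _m, _c] = _phase_one(_f, _m, _c)


def mendelian_phase(g_father: np.ndarray, g_mother: np.ndarray,
                    g_child: np.ndarray) -> PhasedChild:
    """Phase one child by Mendelian rules (vectorized over sites)."""
    gf = np.asarray(g_father, dtype=np.int8)
    gm = np.asarray(g_mother, dtype=np.int8)
    gc = np.asarray(g_child, dtype=np.int8)
    for g in (gf, gm, gc):
        if not np.isin(g, (-1, 0, 1, 2)).all():
            raise ValueError("genotypes must be in {0, 1, 2} or -1 for missing")
    out = _LUT[gf, gm, gc]
    return PhasedChild(h_pat=out[..., 0].copy(), h_mat=out[..., 1].copy(),
                       resolved_by=out[..., 2].astype(np.uint8))


def mendelian_error_mask(g_father, g_mother, g_child) -> np.ndarray:
    """True where the trio genotypes are Mendelian-incompatible."""
    gf = np.asarray(g_father, np.int8)
    gm = np.asarray(g_mother, np.int8)
    gc = np.asarray(g_child, np.int8)
    ok = np.zeros((4, 4, 4), dtype=bool)
    for f in (-1, 0, 1, 2):
        for m in (-1, 0, 1, 2):
            for c in (-1, 0, 1, 2):
                ok[f, m, c] = c == MISSING or any(
                    c - p in (0, 1) and p in _alleles(f) and (c - p) in _alleles(m)
                    for p in (0, 1)
                )
    return ~ok[gf, gm, gc]


# ---------------------------------------------------------------------------
# Li-Stephens forward-backward imputation
# ---------------------------------------------------------------------------

class LiStephensHMM:
    """Haplotype-copying HMM over a reference panel.

    States are panel haplotypes; the chain switches template with
    probability ``rho`` per interval (uniformly, including self) and each
    observed allele is a copy of the template allele with error ``eps``.
    The posterior alt-allele dosage at a masked site is
    sum_h gamma(h) * P(allele=1 | template h).
    """

    def __init__(self, params: HmmParams):
        self.params = params

    def _emissions(self, haps: np.ndarray) -> np.ndarray:
        """(T, B, H) emission probabilities; missing observation emits 1."""
        panel = self.params.panel  # (H, S)
        eps = self.params.eps
        obs = haps[:, :, None]              # (B, S, 1)
        pan = panel.T[None, :, :]           # (1, S, H)
        E = np.where(pan == MISSING, 0.5,
                     np.where(obs == pan, 1.0 - eps, eps))
        E = np.where(obs == MISSING, 1.0, E)
        return np.ascontiguousarray(E.transpose(1, 0, 2))  # (S, B, H)

    def posterior_dosages(self, haps: np.ndarray,
                          allow_mask: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele dosage in [0, 1] per (haplotype, site).

        ``haps`` is (B, S) with -1 at masked sites; observed sites are
        passed through unchanged. ``allow_mask`` (B, H) optionally restricts
        the copying prior of each query to a subset of panel haplotypes.
        """
        haps = np.atleast_2d(np.asarray(haps, np.int8))
        panel = self.params.panel
        B, S = haps.shape
        H = panel.shape[0]
        if S != panel.shape[1]:
            raise ValueError("haplotype length must equal panel site count")
        if allow_mask is None:
            w = np.full((B, H), 1.0 / H)
        else:
            allow = np.asarray(allow_mask, bool)
            if not allow.any(axis=1).all():
                raise ValueError("every query needs at least one allowed template")
            w = allow / allow.sum(axis=1, keepdims=True)
        rho = self.params.rho
        eps = self.params.eps

        E = self._emissions(haps)  # (S, B, H)
        alpha = np.empty((S, B, H))
        a = w * E[0]
        norm = a.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        alpha[0] = a / norm
        for t in range(1, S):
            a = E[t] * ((1 - rho) * alpha[t - 1] + rho * w)
            nrm = a.sum(axis=1, keepdims=True)
            nrm[nrm == 0] = 1.0
            alpha[t] = a / nrm

        # backward pass writes the posteriors gamma into the alpha buffer
        gamma = alpha
        b = np.ones((B, H))
        for t in range(S - 2, -1, -1):
            eb = E[t + 1] * b
            b = (1 - rho) * eb + rho * (w * eb).sum(axis=1, keepdims=True)
            nrm = b.sum(axis=1, keepdims=True)
            nrm[nrm == 0] = 1.0
            b = b / nrm
            g = alpha[t] * b
            gn = g.sum(axis=1, keepdims=True)
            gn[gn == 0] = 1.0
            gamma[t] = g / gn

        p_alt = np.where(panel.T[None] == MISSING, 0.5,
                         np.where(panel.T[None] == 1, 1.0 - eps, eps))  # (1,S,H)
        dos = np.einsum("sbh,sh->bs", gamma, p_alt[0])
        observed = haps != MISSING
        out = np.where(observed, haps.astype(float), dos)
        return out


def impute_dosage(haplotype: np.ndarray, params: HmmParams,
                  allow_mask: np.ndarray | None = None) -> np.ndarray:
    """Dosage vector for a single haplotype with missing sites."""
    hap = np.asarray(haplotype, np.int8)
    if (hap == MISSING).all() and params.panel.size == 0:
        raise ValueError("cannot impute an all-missing haplotype with an empty panel")
    am = None if allow_mask is None else np.atleast_2d(allow_mask)
    return LiStephensHMM(params).posterior_dosages(hap[None, :], am)[0]


def resolve_triple_het(phased: PhasedChild, pat_dosage: np.ndarray,
                       mat_dosage: np.ndarray,
                       rng: np.random.Generator | None = None) -> PhasedChild:
    """Fill remaining missing alleles by dosage comparison.

    At sites where both haplotypes are missing the larger dosage gets
    allele 1 and the other allele 0 (ties broken by a seeded coin flip).
    Sites with exactly one missing haplotype are thresholded at 0.5.
    Mendelian-resolved sites are never altered.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    h_pat = phased.h_pat.copy()
    h_mat = phased.h_mat.copy()
    tags = phased.resolved_by.copy()
    pd_, md_ = np.asarray(pat_dosage, float), np.asarray(mat_dosage, float)

    both = (h_pat == MISSING) & (h_mat == MISSING)
    if both.any():
        if np.isnan(pd_[both]).any() or np.isnan(md_[both]).any():
            raise ValueError("dosages required at every missing site")
        tie = both & (pd_ == md_)
        pat_gets_alt = np.where(tie, rng.random(both.shape) < 0.5, pd_ > md_)
        h_pat[both] = np.where(pat_gets_alt[both], 1, 0)
        h_mat[both] = np.where(pat_gets_alt[both], 0, 1)
        newtag = np.where(tags == ERROR_MASKED, ERROR_MASKED, IMPUTED)
        tags[both] = newtag[both]

    for h, d in ((h_pat, pd_), (h_mat, md_)):
        solo = h == MISSING
        if solo.any():
            gt = d[solo] > 0.5
            eq = d[solo] == 0.5
            fill = np.where(eq, rng.random(eq.shape) < 0.5, gt)
            h[solo] = fill.astype(np.int8)
            tags[solo] = np.where(tags[solo] == ERROR_MASKED, ERROR_MASKED, IMPUTED)

    return PhasedChild(h_pat, h_mat, tags, pat_dosage=pd_, mat_dosage=md_)


def phasing_error_rate(truth_pat: np.ndarray, inferred_pat: np.ndarray,
                       triple_het_mask: np.ndarray) -> float | None:
    """Fraction of triple-het sites whose parental assignment is wrong.

    Comparison is on the paternal haplotype only: at a (heterozygous-child)
    triple-het site the maternal allele is determined by the paternal one.
    Returns None when there are no triple-het sites (rate undefined).
    """
    m = np.asarray(triple_het_mask, bool)
    if m.sum() == 0:
        return None
    t = np.asarray(truth_pat)[m]
    i = np.asarray(inferred_pat)[m]
    return float(np.mean(t != i))


# ---------------------------------------------------------------------------
# Dataset-level phasing
# ---------------------------------------------------------------------------

def build_parent_panel(g_father, g_mother, phased: list[PhasedChild]):
    """Reference haplotypes from the trios' own parents.

    The transmitted parental haplotype equals the child haplotype; the
    untransmitted one is genotype minus transmitted allele (missing where
    either is unknown). Returns (panel (4*n_trios, S), owner trio index per
    panel haplotype).
    """
    haps, owner = [], []
    for i, ph in enumerate(phased):
        for g_par, trans in ((g_father[i], ph.h_pat), (g_mother[i], ph.h_mat)):
            un = np.where((trans != MISSING) & (g_par != MISSING),
                          g_par - trans, MISSING).astype(np.int8)
            un[(un != MISSING) & ((un < 0) | (un > 1))] = MISSING  # error sites
            haps.extend([trans, un])
            owner.extend([i, i])
    return np.array(haps, dtype=np.int8), np.array(owner)


def phase_trio_dataset(g_father, g_mother, g_child, *, rho: float = 0.005,
                       eps: float = 0.001, max_panel: int = 200,
                       seed: int = 0, chunk: int = 32):
    """Phase every child in a trio dataset; self-contained reference panel.

    Mendelian phasing first; the imputation panel is built from the
    parents' Mendelian-phased haplotypes, subsampled to ``max_panel``
    haplotypes, with each child's own parents excluded from its copying
    prior. Returns a list of complete :class:`PhasedChild`.
    """
    rng = np.random.default_rng(seed)
    n = g_child.shape[0]
    phased = [mendelian_phase(g_father[i], g_mother[i], g_child[i])
              for i in range(n)]
    panel, owner = build_parent_panel(g_father, g_mother, phased)
    if panel.shape[0] > max_panel:
        keep = rng.choice(panel.shape[0], size=max_panel, replace=False)
        panel, owner = panel[keep], owner[keep]
    params = HmmParams(panel=panel, rho=rho, eps=eps)
    hmm = LiStephensHMM(params)

    out: list[PhasedChild] = []
    for start in range(0, n, chunk):
        idx = range(start, min(start + chunk, n))
        queries = np.concatenate([
            np.stack([phased[i].h_pat, phased[i].h_mat]) for i in idx
        ])
        allow = np.ones((len(queries), panel.shape[0]), bool)
        for k, i in enumerate(idx):
            allow[2 * k:2 * k + 2, owner == i] = False
        dos = hmm.posterior_dosages(queries, allow)
        for k, i in enumerate(idx):
            out.append(resolve_triple_het(
                phased[i], dos[2 * k], dos[2 * k + 1], rng=rng))
    return out
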