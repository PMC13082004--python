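"""Structural contact analysis: contact-map binarization, haplotype vs
reference contact diffs, enrichment of strong sensitization interactions at
contacts, population-weighted contact maps, and the confidence/variability
correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONTACT_THRESHOLD = 8.0  # Angstrom, strict '<'


@dataclass
class ContactMap:
    contacts: np.ndarray  # symmetric boolean, false diagonal
    source: str
    threshold: float = CONTACT_THRESHOLD

    @property
    def n_residues(self) -> int:
        return self.contacts.shape[0]

    def pairs(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.contacts, k=1))
        return set(zip(i.tolist(), j.tolist()))


def binarize_contacts(distance_map, threshold: float = CONTACT_THRESHOLD,
                      source: str = "reference",
                      symmetry_tol: float = 1e-6) -> ContactMap:
    """Contacts are residue pairs with distance strictly below the
    threshold, excluding the diagonal."""
    d = np.asarray(distance_map, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance map must be square")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if np.abs(d - d.T).max() > symmetry_tol:
        raise ValueError("distance map asymmetric beyond tolerance")
    contacts = d < threshold
    np.fill_diagonal(contacts, False)
    return ContactMap(contacts=contacts, source=source, threshold=threshold)


@dataclass
class ContactDiff:
    gained: set[tuple[int, int]]
    lost: set[tuple[int, int]]
    gained_fraction: float
    lost_fraction: float


def contact_diff(hap_contacts: ContactMap, ref_contacts: ContactMap) -> ContactDiff:
    """Contacts gained/lost by a haplotype relative to the reference;
    fractions are over all residue pairs i < j.  Indel-bearing haplotypes
    (residue-count mismatch) must be excluded upstream."""
    if hap_contacts.n_residues != ref_contacts.n_residues:
        raise ValueError(
            "residue count mismatch (indel-bearing haplotype?); contact "
            "diffs are defined for equal-length haplotypes only"
        )
    hap, ref = hap_contacts.pairs(), ref_contacts.pairs()
    n = hap_contacts.n_residues
    total = n * (n - 1) // 2
    gained, lost = hap - ref, ref - hap
    return ContactDiff(
        gained=gained, lost=lost,
        gained_fraction=len(gained) / total,
        lost_fraction=len(lost) / total,
    )


@dataclass
class EnrichmentCurve:
    thresholds: np.ndarray
    enrichment: np.ndarray  # E(t), NaN where undefined
    n_pairs: np.ndarray  # pairs with |beta| > t
    n_contact: np.ndarray  # of those, in contact
    binom_p: np.ndarray
    p_exp: float  # overall contact frequency among mapped pairs
    n_excluded: int = 0  # pairs without a residue mapping


def contact_enrichment(
    beta_matrix: np.ndarray,
    contacts: ContactMap,
    pair_position_map,
    thresholds=None,
    n_quantiles: int = 20,
) -> EnrichmentCurve:
    """Observed/expected enrichment of strong interactions at contacts.

    ``pair_position_map[(i, j)]`` maps a (background index, clinical index)
    coefficient cell to a residue pair; unmapped cells are excluded (count
    recorded).  E(t) = p_obs(t) / p_exp where p_obs(t) is the contact
    fraction among pairs with |beta| > t and p_exp the overall contact
    frequency; per-threshold significance from a one-sided binomial test.
    """
    beta = np.asarray(beta_matrix, dtype=float)
    abs_beta, in_contact = [], []
    n_excluded = 0
    for (bi, cj), residues in pair_position_map.items():
        if residues is None:
            n_excluded += 1
            continue
        ri, rj = residues
        abs_beta.append(abs(beta[bi, cj]))
        in_contact.append(bool(contacts.contacts[ri, rj]))
    abs_beta = np.asarray(abs_beta)
    in_contact = np.asarray(in_contact, dtype=bool)
    if abs_beta.size == 0:
        raise ValueError("no mapped variant pairs")
    p_exp = in_contact.mean()
    if thresholds is None:
        qs = np.linspace(0.0, 1.0, n_quantiles, endpoint=False)
        thresholds = np.unique(np.quantile(abs_beta, qs))
        # include an all-inclusive threshold below every |beta|
        thresholds = np.concatenate([[-1e-12], thresholds[:-1]]) \
            if thresholds.size else np.array([-1e-12])
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    enrichment = np.full(thresholds.size, np.nan)
    n_pairs = np.zeros(thresholds.size, dtype=int)
    n_contact = np.zeros(thresholds.size, dtype=int)
    binom_p = np.full(thresholds.size, np.nan)
    for k, t in enumerate(thresholds):
        sel = abs_beta > t
        n_pairs[k] = int(sel.sum())
        if n_pairs[k] == 0:
            continue
        n_contact[k] = int(in_contact[sel].sum())
        p_obs = n_contact[k] / n_pairs[k]
        if p_exp > 0:
            enrichment[k] = p_obs / p_exp
            binom_p[k] = stats.binomtest(
                n_contact[k], n_pairs[k], p_exp, alternative="greater"
            ).pvalue
    return EnrichmentCurve(
        thresholds=thresholds, enrichment=enrichment, n_pairs=n_pairs,
        n_contact=n_contact, binom_p=binom_p, p_exp=float(p_exp),
        n_excluded=n_excluded,
    )


@dataclass
class WeightedContacts:
    group: str
    weighted: np.ndarray  # in [0, 1]
    calls: np.ndarray  # boolean group-level contacts (weighted > threshold)
    gained: int
    lost: int


def population_weighted_contacts(
    hap_contact_maps: list[ContactMap],
    hap_frequencies_per_group: dict[str, np.ndarray],
    ref_contacts: ContactMap,
    call_threshold: float = 0.5,
) -> dict[str, WeightedContacts]:
    """Per-superpopulation frequency-weighted contact maps.

    W = sum_h f_h * C_h; a group-level contact is called where W strictly
    exceeds ``call_threshold`` (majority of chromosome mass); gained/lost
    counts are against the reference contact calls.
    """
    mats = np.stack([m.contacts.astype(float) for m in hap_contact_maps])
    out: dict[str, WeightedContacts] = {}
    ref = ref_contacts.contacts
    for group, freqs in sorted(hap_frequencies_per_group.items()):
        f = np.asarray(freqs, dtype=float)
        if f.shape[0] != mats.shape[0]:
            raise ValueError(f"group {group}: frequency count mismatch")
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError(f"group {group}: frequencies sum to {f.sum()}")
        W = np.tensordot(f, mats, axes=1)
        calls = W > call_threshold
        np.fill_diagonal(calls, False)
        upper = np.triu(np.ones_like(ref, dtype=bool), k=1)
        gained = int((calls & ~ref & upper).sum())
        lost = int((~calls & ref & upper).sum())
        out[group] = WeightedContacts(group=group, weighted=W, calls=calls,
                                      gained=gained, lost=lost)
    return out


def contact_variance_profile(hap_contact_maps: list[ContactMap]) -> np.ndarray:
    """Per-residue structural variability: the across-haplotype variance of
    each contact indicator, averaged over partner residues."""
    if len(hap_contact_maps) < 2:
        raise ValueError("need at least 2 haplotype maps")
    mats = np.stack([m.contacts.astype(float) for m in hap_contact_maps])
    var = mats.var(axis=0)  # population variance per residue pair
    return var.mean(axis=1)


def confidence_variance_correlation(
    hap_contact_maps: list[ContactMap],
    per_residue_confidence,
):
    """Pearson correlation between per-residue contact variability and
    per-residue confidence.  Returns (r, p) or None when the variability
    profile is constant (correlation undefined, flagged)."""
    profile = contact_variance_profile(hap_contact_maps)
    conf = np.asarray(per_residue_confidence, dtype=float)
    if conf.shape[0] != profile.shape[0]:
        raise ValueError("confidence length must match residue count")
    if np.ptp(profile) == 0 or np.ptp(conf) == 0:
        return None
    r, p = stats.pearsonr(profile, conf)
    return float(r), float(p)


def enrichment_frame(curve: EnrichmentCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "threshold": curve.thresholds,
        "enrichment": curve.enrichment,
        "n_pairs": curve.n_pairs,
        "n_contact": curve.n_contact,
        "binom_p": curve.binom_p,
        "p_exp": curve.p_exp,
    })
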