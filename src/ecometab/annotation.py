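"""Formula/adduct mass annotation and pathway over-representation.

Differential features (dMEs) are assigned tentative metabolite identities
(tMEs, identification level 3) by comparing the observed m/z against the
theoretical m/z of every (compound, adduct) combination from a local
compound reference, within a +/-5 ppm mass-accuracy window.  Annotated
KEGG IDs are then tested for pathway over-representation with an exact
hypergeometric tail and with a Mummichog-style permutation null in which
random m/z lists of the same size are re-annotated through the same
matching machinery.

All arithmetic is on neutral monoisotopic masses; adducts are fixed,
electron-corrected mass shifts for singly charged ions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# Monoisotopic atomic masses (Da), IUPAC/CODATA.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990907
_PROTON = ATOMIC_MASS["H"] - ELECTRON_MASS           # +1.007276
_WATER = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]     # 18.010565
_FORMIC = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["O"]  # 46.005479


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged adduct: name, signed mass shift (Da), charge sign."""

    name: str
    mass_shift: float
    charge: int  # +1 or -1


#: Electron-corrected shifts for the adduct forms seen in plant ESI data.
ADDUCTS: dict[str, AdductSpec] = {
    a.name: a
    for a in (
        AdductSpec("[M+H]+", _PROTON, +1),
        AdductSpec("[M+Na]+", ATOMIC_MASS["Na"] - ELECTRON_MASS, +1),
        AdductSpec("[M+H-H2O]+", _PROTON - _WATER, +1),
        AdductSpec("[M-H]-", -_PROTON, -1),
        AdductSpec("[M+Cl]-", ATOMIC_MASS["Cl"] + ELECTRON_MASS, -1),
        AdductSpec("[M+FA-H]-", _FORMIC - _PROTON, -1),
        AdductSpec("[M-H2O-H]-", -_WATER - _PROTON, -1),
    )
}

POSITIVE_ADDUCTS = tuple(a for a, s in ADDUCTS.items() if s.charge > 0)
NEGATIVE_ADDUCTS = tuple(a for a, s in ADDUCTS.items() if s.charge < 0)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """A molecular formula string could not be parsed."""


def parse_formula(s: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    Underscore-decorated variants (``C_16_H_18_O_9_``) as they appear in
    some table exports are accepted.  Elements outside the supported set
    are rejected.
    """
    clean = s.replace("_", "").strip()
    if not clean:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(clean):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula {s!r} at {clean[pos:]!r}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in ATOMIC_MASS:
            raise FormulaError(f"unsupported element {elem!r} in formula {s!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(clean):
        raise FormulaError(f"unparseable formula {s!r} at {clean[pos:]!r}")
    return counts


def monoisotopic_mass(counts: Mapping[str, int] | str) -> float:
    """Neutral monoisotopic mass (Da) of a formula or element-count map."""
    if isinstance(counts, str):
        counts = parse_formula(counts)
    return float(sum(ATOMIC_MASS[e] * n for e, n in counts.items()))


def adduct_mz(mass: float, adduct: str | AdductSpec) -> float:
    """Theoretical m/z of a neutral mass under a singly charged adduct."""
    if mass <= 0:
        raise ValueError("neutral mass must be positive")
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    return mass + adduct.mass_shift


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# Compound / pathway references
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    name: str
    formula: str
    kegg_id: str
    source: str = ""

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.formula)


def load_compounds(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load a compound reference TSV (name, formula, kegg_id).

    With no path, the bundled plant secondary-metabolite reference is
    used.
    """
    if path is None:
        path = resources.files("ecometab.data") / "compounds.tsv"
    df = pd.read_csv(path, sep="\t")
    recs = [
        CompoundRecord(
            name=r["name"], formula=r["formula"], kegg_id=r["kegg_id"],
            source=str(r.get("source", "")),
        )
        for r in df.to_dict("records")
    ]
    bad = [r.kegg_id for r in recs if not parse_formula(r.formula)]
    if bad:
        raise FormulaError(f"empty formulas for {bad}")
    return recs


def load_pathways(path: str | Path | None = None) -> dict[str, dict]:
    """Load GMT pathway sets: pathway_id -> {name, compounds}."""
    if path is None:
        path = resources.files("ecometab.data") / "pathways.gmt"
    pathways: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, name, *members = line.split("\t")
            pathways[pid] = {"name": name, "compounds": set(members)}
    return pathways


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_features(
    feature_mzs: Mapping[str, float] | Sequence[str],
    reference: Sequence[CompoundRecord],
    adducts: Sequence[str] = POSITIVE_ADDUCTS,
    tol_ppm: float = 5.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Match observed feature m/z values against a compound reference.

    Parameters
    ----------
    feature_mzs:
        Either a mapping label -> observed m/z, or a sequence of
        ``<mz>_<rt>`` labels (parsed for their m/z).
    reference, adducts, tol_ppm:
        Candidate compounds, adduct forms to consider, and the mass
        accuracy window in ppm (default +/-5, identification level 3).

    Returns
    -------
    (candidates, unmatched):
        ``candidates`` holds one row per (feature, compound, adduct) hit
        within tolerance, sorted by feature then |ppm|; ``unmatched``
        lists features with no candidate.
    """
    if not len(reference):
        raise ValueError("empty compound reference")
    if not len(adducts):
        raise ValueError("empty adduct list")
    if not isinstance(feature_mzs, Mapping):
        from .feature_io import parse_feature_id

        feature_mzs = {lbl: parse_feature_id(lbl).mz for lbl in feature_mzs}

    theo = np.array(
        [[adduct_mz(c.monoisotopic_mass, a) for a in adducts] for c in reference]
    )  # compounds x adducts
    rows = []
    unmatched = []
    for label, mz in feature_mzs.items():
        err = (mz - theo) / theo * 1e6
        hit_c, hit_a = np.nonzero(np.abs(err) <= tol_ppm)
        if hit_c.size == 0:
            unmatched.append(label)
            continue
        for ci, ai in zip(hit_c, hit_a):
            comp = reference[ci]
            rows.append(
                {
                    "feature": label,
                    "observed_mz": mz,
                    "compound": comp.name,
                    "formula": comp.formula,
                    "kegg_id": comp.kegg_id,
                    "adduct": adducts[ai],
                    "theoretical_mz": theo[ci, ai],
                    "ppm_error": err[ci, ai],
                    "level": 3,
                }
            )
    candidates = pd.DataFrame(
        rows,
        columns=[
            "feature", "observed_mz", "compound", "formula", "kegg_id",
            "adduct", "theoretical_mz", "ppm_error", "level",
        ],
    )
    if len(candidates):
        candidates["abs_ppm"] = candidates["ppm_error"].abs()
        candidates = (
            candidates.sort_values(["feature", "abs_ppm"], kind="stable")
            .drop(columns="abs_ppm")
            .reset_index(drop=True)
        )
    return candidates, unmatched


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k: int          # annotated hits in pathway
    m: int          # pathway size within the universe
    n_sig: int      # size of the significant (dME) list
    N: int          # universe size
    p_exact: float
    p_perm: float | None = None
    n_perm: int = 0
    seed: int | None = None


def hypergeom_tail(k: int, N: int, m: int, n_sig: int) -> float:
    """Upper-tail P(X >= k) for drawing n_sig items from N with m marked."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m, n_sig))


def pathway_enrichment(
    hit_kegg_ids: Iterable[str],
    pathways: Mapping[str, dict],
    universe: Iterable[str],
    *,
    feature_mzs: Mapping[str, float] | None = None,
    n_features_sig: int | None = None,
    reference: Sequence[CompoundRecord] | None = None,
    adducts: Sequence[str] = POSITIVE_ADDUCTS,
    tol_ppm: float = 5.0,
    n_perm: int = 0,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Pathway over-representation of annotated significant compounds.

    ``p_exact`` is the hypergeometric upper tail over the compound
    universe.  When ``n_perm`` > 0 and the full detected feature list is
    supplied (``feature_mzs``), a Mummichog-style permutation p-value is
    added: random feature lists of the significant-list size are drawn
    from all detected features, re-annotated through
    :func:`match_features`, and the fraction achieving >= k hits in the
    pathway is reported (add-one corrected).
    """
    hits = set(hit_kegg_ids)
    universe = set(universe)
    if not hits:
        raise ValueError("empty significant list")
    N = len(universe)
    n_sig = len(hits & universe)

    results: list[EnrichmentResult] = []
    for pid, pw in pathways.items():
        members = set(pw["compounds"]) & universe
        m = len(members)
        if m == 0:
            logger.warning("pathway %s has no members in the universe; skipped", pid)
            continue
        k = len(hits & members)
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                pathway_name=pw.get("name", pid),
                k=k, m=m, n_sig=n_sig, N=N,
                p_exact=hypergeom_tail(k, N, m, n_sig),
            )
        )

    if n_perm > 0:
        if feature_mzs is None or reference is None or n_features_sig is None:
            raise ValueError(
                "permutation p-values need feature_mzs, reference and n_features_sig"
            )
        rng = np.random.default_rng(seed)
        labels = list(feature_mzs)
        mzs = np.array([feature_mzs[l] for l in labels])
        size = min(n_features_sig, len(labels))
        exceed = {r.pathway_id: 0 for r in results}
        members_by_pw = {
            r.pathway_id: set(pathways[r.pathway_id]["compounds"]) for r in results
        }
        for _ in range(n_perm):
            pick = rng.choice(len(labels), size=size, replace=False)
            cand, _ = match_features(
                {labels[i]: mzs[i] for i in pick}, reference, adducts, tol_ppm
            )
            perm_ids = set(cand["kegg_id"]) if len(cand) else set()
            for r in results:
                if len(perm_ids & members_by_pw[r.pathway_id]) >= r.k:
                    exceed[r.pathway_id] += 1
        for r in results:
            r.p_perm = (exceed[r.pathway_id] + 1) / (n_perm + 1)
            r.n_perm = n_perm
            r.seed = seed

    results.sort(key=lambda r: (r.p_perm if r.p_perm is not None else r.p_exact, r.p_exact))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "pathway_name": r.pathway_name,
                "hits": r.k,
                "pathway_size": r.m,
                "n_sig": r.n_sig,
                "universe": r.N,
                "p_exact": r.p_exact,
                "p_perm": r.p_perm,
            }
            for r in results
        ]
    )


def build_report(
    annotations: pd.DataFrame, pathways: Mapping[str, dict]
) -> pd.DataFrame:
    """Long-format pathway x tME mapping table (Circos-ready).

    One row per (pathway, annotated feature) pair; a tME belonging to
    several pathways appears once per pathway.
    """
    rows = []
    for pid, pw in pathways.items():
        members = set(pw["compounds"])
        sub = annotations[annotations["kegg_id"].isin(members)]
        for r in sub.to_dict("records"):
            rows.append(
                {
                    "pathway_id": pid,
                    "pathway_name": pw.get("name", pid),
                    "feature": r["feature"],
                    "compound": r["compound"],
                    "kegg_id": r["kegg_id"],
                    "adduct": r["adduct"],
                    "ppm_error": r["ppm_error"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "pathway_name", "feature", "compound",
            "kegg_id", "adduct", "ppm_error",
        ],
    )
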