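"""Metabolite-family presence calling from per-strain feature detections.

An MF (metabolite family) groups LC-MS features attributed to structurally
related compounds.  The presence rule: an MF is present in a strain iff at
least 3% of the MF's features were detected in that strain AND at least one
detected feature carries the protonated-molecular-ion adduct [M+H]+ (a
feature seen only as e.g. a sodium adduct or in-source fragment is weaker
evidence the compound itself is there).  The 3% threshold is evaluated with
exact rational arithmetic so the boundary (exactly 3%) is reproducibly
"present".  A feature counts as detected in a strain if it was detected in
at least one replicate (configurable to majority-of-replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .io import PhylolinkError, TraitMatrix, ValidationError

__all__ = [
    "MFCatalog",
    "read_feature_table",
    "call_mf_presence",
    "CANONICAL_PROTON_ADDUCT",
]

CANONICAL_PROTON_ADDUCT = "[M+H]+"

FEATURE_COLUMNS = ["feature_id", "mf_id", "adduct", "strain_id", "replicate_id", "detected"]


@dataclass
class MFCatalog:
    """MF id -> member feature ids, plus the presence thresholds."""

    members: dict[str, set[str]]
    fraction: Fraction = Fraction(3, 100)
    min_proton_features: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValidationError("fraction threshold must be in (0, 1]")
        for mf_id, feats in self.members.items():
            if not feats:
                raise ValidationError(f"MF {mf_id!r} has zero features")

    @classmethod
    def from_features(cls, features: pd.DataFrame, **kw) -> "MFCatalog":
        members: dict[str, set[str]] = {}
        for mf_id, fid in zip(features["mf_id"], features["feature_id"]):
            members.setdefault(str(mf_id), set()).add(str(fid))
        return cls(members=members, **kw)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-detection TSV (feature_id, mf_id, adduct, strain_id,
    replicate_id, detected)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"feature table missing columns: {sorted(missing)}")
    df["detected"] = pd.to_numeric(df["detected"])
    if not df["detected"].isin((0, 1)).all():
        raise ValidationError("detected flag must be 0/1")
    for col in ("feature_id", "mf_id", "adduct", "strain_id", "replicate_id"):
        df[col] = df[col].astype(str).str.strip()
    return df


def call_mf_presence(
    features: pd.DataFrame,
    catalog: MFCatalog | None = None,
    strains: list[str] | None = None,
    replicate_rule: str = "any",
    adduct_synonyms: dict[str, str] | None = None,
    count_unit: str = "feature",
) -> TraitMatrix:
    """Call the binary MF presence matrix from feature detections.

    Parameters
    ----------
    features : DataFrame
        Long-format detections with the columns of ``FEATURE_COLUMNS``.
    catalog : MFCatalog, optional
        Defaults to the catalog implied by the feature table itself.
    strains : list of str, optional
        Output strains; defaults to those appearing in the table.  Strains
        listed but without detections get explicit zero rows.
    replicate_rule : "any" or "majority"
        A feature is detected in a strain if detected in >= 1 replicate
        ("any", default) or in more than half of its replicates.
    adduct_synonyms : dict, optional
        Maps dialect adduct spellings onto canonical ones (e.g.
        ``{"M+H": "[M+H]+"}``) before matching.
    count_unit : "feature"
        Distinct features are counted toward the 3% rule (feature x adduct
        combinations are not double-counted); kept explicit because the
        alternative reading exists.
    """
    if count_unit != "feature":
        raise ValueError("only count_unit='feature' is supported")
    if replicate_rule not in ("any", "majority"):
        raise ValueError("replicate_rule must be 'any' or 'majority'")
    df = features.copy()
    if catalog is None:
        catalog = MFCatalog.from_features(df)
    known = set(catalog.members)
    unknown = set(df["mf_id"]) - known
    if unknown:
        raise PhylolinkError(f"features reference unknown MFs: {sorted(unknown)}")
    syn = adduct_synonyms or {}
    df["adduct"] = df["adduct"].str.strip().map(lambda a: syn.get(a, a))
    if (df["adduct"] == "").any():
        raise ValidationError("empty adduct label")

    # merge replicates -> per (strain, mf, feature) detection
    grp = df.groupby(["strain_id", "mf_id", "feature_id"], sort=False)["detected"]
    if replicate_rule == "any":
        det = grp.max()
    else:
        det = (grp.mean() > 0.5).astype(int)
    det = det.reset_index(name="detected")
    # a feature's adduct is constant across rows; carry it along
    adduct_of = df.drop_duplicates("feature_id").set_index("feature_id")["adduct"]
    det["is_proton"] = det["feature_id"].map(adduct_of).eq(CANONICAL_PROTON_ADDUCT)

    if strains is None:
        strains = list(dict.fromkeys(df["strain_id"]))
    mf_ids = sorted(catalog.members)
    mf_size = {m: len(catalog.members[m]) for m in mf_ids}

    detected = det[det["detected"] == 1]
    counts = detected.groupby(["strain_id", "mf_id"], sort=False).agg(
        n_detected=("feature_id", "nunique"),
        n_proton=("is_proton", "sum"),
    )
    data = pd.DataFrame(0, index=pd.Index(strains, name="strain_id"), columns=mf_ids,
                        dtype=int)
    for (strain, mf_id), row in counts.iterrows():
        if strain not in data.index:
            continue
        frac_ok = Fraction(int(row["n_detected"]), mf_size[mf_id]) >= catalog.fraction
        proton_ok = int(row["n_proton"]) >= catalog.min_proton_features
        if frac_ok and proton_ok:
            data.loc[strain, mf_id] = 1
    return TraitMatrix(data, "MF")
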