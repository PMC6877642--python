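"""Per-decay dose normalization, absorbed fractions and organ-dose reports.

Transport tallies are per source emission (one emission per history).
Converting to per-decay quantities multiplies by the total emission yield
of that radiation kind; organ dose is then energy per organ mass times
the unit conversion 1 MeV/g = 160.2 pGy, giving pGy per Bq·s (one decay
per second for one second).

Reference context: per-organ doses and heart/lung ratios depend strongly
on the anatomy of the phantom used; the report can print literature
values for a segmented adult-male reference phantom next to the computed
values for orientation — they are context, not assertions about this
phantom.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclides import Nuclide
from .transport.tally import OrganTally

__all__ = [
    "MEV_PER_G_TO_PGY",
    "per_decay_scale",
    "dose_to_pGy",
    "absorbed_fraction",
    "build_dose_report",
    "DoseReport",
    "REFERENCE_HEART_LUNG_RATIOS",
    "REFERENCE_PHOTON_ABSORBED_FRACTIONS",
]

#: 1 MeV = 1.602176634e-13 J; 1 MeV/g = 1.602...e-10 Gy = 160.2 pGy
MEV_PER_G_TO_PGY = 1.602176634e-13 / 1e-3 * 1e12

#: literature heart-wall / lung dose-per-decay ratios on a segmented
#: adult-male reference phantom (context only; anatomy-specific)
REFERENCE_HEART_LUNG_RATIOS = {
    "I-131": 0.50,
    "Cs-137": 0.55,
    "Cs-134": 0.77,
    "Ru-103": 0.77,
    "Sr-90/Y-90": 0.40,
}

#: literature whole-body photon absorbed fractions on the same reference
REFERENCE_PHOTON_ABSORBED_FRACTIONS = {
    "I-131": 0.46,
    "Cs-137": 0.44,
    "Cs-134": 0.44,
    "Ru-103": 0.45,
}


def per_decay_scale(tally_per_history, nuclide: Nuclide, kind: str):
    """Multiply a per-emission tally by the emissions per decay of ``kind``."""
    y = nuclide.total_yield("photon" if kind in ("gamma", "xray") else kind)
    arr = np.asarray(tally_per_history, float)
    if y == 0.0:
        import warnings

        warnings.warn(f"{nuclide.name} has zero {kind} yield; per-decay tally is zero")
        return np.zeros_like(arr)
    return arr * y


def dose_to_pGy(dose_MeV_per_g):
    """Convert MeV/g per decay to pGy per Bq·s (×160.2)."""
    d = np.asarray(dose_MeV_per_g, float)
    if np.any(d < 0):
        raise ValueError("dose cannot be negative")
    return d * MEV_PER_G_TO_PGY


def absorbed_fraction(tally: OrganTally, phantom, emitted_MeV: float) -> float:
    """Fraction of emitted energy deposited in body tissue (air excluded)."""
    if emitted_MeV <= 0:
        raise ValueError("no energy emitted")
    tissue = np.array(
        [phantom.organ_materials[int(i)].density_g_cc > 0.01 for i in tally.organ_ids]
    )
    return float(tally.energy_MeV[tissue].sum() / emitted_MeV)


@dataclass
class DoseReport:
    """Organ-resolved per-decay dose summary for one nuclide."""

    nuclide: str
    table: pd.DataFrame  # organ, mass_g, per-kind + total dose, rel_err
    absorbed_fractions: dict[str, float]
    heart_lung_ratio: float | None
    provenance: dict = field(default_factory=dict)
    reference_context: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "nuclide": self.nuclide,
            "organs": self.table.to_dict(orient="records"),
            "absorbed_fractions": self.absorbed_fractions,
            "heart_lung_ratio": self.heart_lung_ratio,
            "provenance": self.provenance,
            "reference_context": self.reference_context,
        }
        text = json.dumps(payload, indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [f"Per-decay organ dose for {self.nuclide} (pGy/Bq·s)"]
        cols = [c for c in self.table.columns if c.endswith("_pGy_per_Bq_s")]
        for _, row in self.table.sort_values("total_pGy_per_Bq_s", ascending=False).iterrows():
            vals = "  ".join(f"{row[c]:.3e}" for c in cols)
            lines.append(f"  {row['organ']:<14s} m={row['mass_g']:9.1f} g  {vals}")
        for kind, af in self.absorbed_fractions.items():
            ref = self.reference_context.get(f"absorbed_fraction_{kind}")
            extra = f"  (reference phantom: {ref})" if ref is not None else ""
            lines.append(f"absorbed fraction ({kind}): {af:.3f}{extra}")
        if self.heart_lung_ratio is not None:
            ref = self.reference_context.get("heart_lung_ratio")
            extra = f"  (reference phantom: {ref})" if ref is not None else ""
            lines.append(f"heart/lung dose ratio: {self.heart_lung_ratio:.3f}{extra}")
        return "\n".join(lines)


def build_dose_report(
    organ_tallies: dict[str, OrganTally],
    phantom,
    nuclide: Nuclide,
    emitted_MeV: dict[str, float] | None = None,
    provenance: dict | None = None,
) -> DoseReport:
    """Assemble the per-decay dose table from per-kind organ tallies.

    ``organ_tallies`` maps radiation kind ('photon', 'beta', 'alpha') to
    its organ tally; ``emitted_MeV`` the corresponding total emitted
    energies (for absorbed fractions).  Organs absent from the phantom are
    simply not listed.
    """
    if not organ_tallies:
        raise ValueError("no transported radiation kinds")
    first = next(iter(organ_tallies.values()))
    ids = first.organ_ids
    names = [phantom.organ_names.get(int(i), str(i)) for i in ids]
    if np.any(first.organ_mass_g <= 0):
        raise ValueError("missing organ masses")
    out = pd.DataFrame({"organ_id": ids, "organ": names, "mass_g": first.organ_mass_g})

    total = np.zeros(len(ids))
    rel_combined = np.zeros(len(ids))
    for kind, tally in organ_tallies.items():
        if not np.array_equal(tally.organ_ids, ids):
            raise ValueError("organ tallies cover different organ sets")
        per_decay = per_decay_scale(tally.dose_MeV_per_g(), nuclide, kind)
        dose = dose_to_pGy(per_decay)
        out[f"{kind}_pGy_per_Bq_s"] = dose
        out[f"{kind}_rel_err"] = tally.relative_errors()
        total += dose
        finite = np.isfinite(out[f"{kind}_rel_err"])
        rel_combined += np.where(finite, (dose * out[f"{kind}_rel_err"]) ** 2, 0.0)
    out["total_pGy_per_Bq_s"] = total
    with np.errstate(divide="ignore", invalid="ignore"):
        out["total_rel_err"] = np.where(total > 0, np.sqrt(rel_combined) / np.where(total > 0, total, 1), np.inf)

    afs = {}
    if emitted_MeV:
        for kind, tally in organ_tallies.items():
            if emitted_MeV.get(kind, 0) > 0:
                afs[kind] = absorbed_fraction(tally, phantom, emitted_MeV[kind])

    def organ_dose(name: str) -> float | None:
        row = out[out["organ"] == name]
        return float(row["total_pGy_per_Bq_s"].iloc[0]) if len(row) else None

    heart, lung = organ_dose("heart_wall"), organ_dose("lung")
    ratio = heart / lung if (heart is not None and lung and lung > 0) else None

    context = {}
    if nuclide.name in REFERENCE_HEART_LUNG_RATIOS:
        context["heart_lung_ratio"] = REFERENCE_HEART_LUNG_RATIOS[nuclide.name]
    if nuclide.name in REFERENCE_PHOTON_ABSORBED_FRACTIONS:
        context["absorbed_fraction_photon"] = REFERENCE_PHOTON_ABSORBED_FRACTIONS[nuclide.name]

    prov = dict(provenance or {})
    prov["config_hash"] = hashlib.sha256(
        json.dumps(prov, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return DoseReport(nuclide.name, out, afs, ratio, prov, context)
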