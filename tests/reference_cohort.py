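"""Reference validation cohort used by the acceptance tests.

Carrier rows for a 113 African + 57 European patient cohort: candidate
id, reporting tier, SV type, patient id, group, age, PSA, ISUP grade
group (None = unknown).  Filler patients complete the cohort so that 93
of the 113 African patients sit at grade group >= 3 and 49 of the 57
European patients at >= 4.
"""

from ppsv.cohort_report import PatientRecord
from ppsv.pathogenicity import PathogenicityCall

N_AFRICAN = 113
N_EUROPEAN = 57

# sv_label, tier, svtype, patient, group, age, psa, isup_gg
CARRIER_ROWS = [
    ("SLC3A1", "clinvar_likely_pathogenic", "DUP", "N0001", "African", 75, 22.9, 4),
    ("SLC3A1", "clinvar_likely_pathogenic", "DUP", "SMU094", "African", 64, 15, 4),
    ("OCA2", "clinvar_likely_pathogenic", "DEL", "N0059", "African", 79, 153, 5),
    ("PIGN", "clinvar_pathogenic", "DEL", "SMU083", "African", 86, 40.5, 3),
    ("SLC7A2", "pp_sv", "DEL", "UP2035", "African", 70, 680, 5),
    ("SLC7A2", "pp_sv", "DEL", "KAL0054", "African", 64, 42.9, 5),
    ("DNAJC15", "pp_sv", "DEL", "17135", "European", 63, 7.8, 5),
    ("BCL2L11", "pp_sv", "DEL", "KAL0101", "African", 71, 32.3, 5),
    ("BARD1", "pp_sv", "DEL", "N0073", "African", 62, None, None),
    ("COL4A2", "pp_sv", "DUP", "UP2039", "African", 71, 319, 4),
    ("SLC2A5", "pp_sv", "DUP", "11099", "European", 70, 9.9, 5),
    ("FOXP1", "pp_sv", "INV", "UP2101", "African", 57, 75, 5),
    ("FOXP1", "pp_sv", "INV", "N0084", "African", 65, 591, 4),
    ("WASF1", "pp_sv", "INV", "N0048", "African", 70, 83.3, 5),
    ("MLH1", "pp_sv", "INV", "SMU080", "African", 64, 23.3, 4),
    ("RB1", "pp_sv", "INV", "SMU064", "African", 70, 13.7, 3),
    ("CTNNA1", "pp_sv", "TRA", "13179", "European", 59, 8.4, 5),
    ("AK8-DST", "pp_sv", "TRA", "11452", "European", 67, 11, 1),
    ("LTBP1-BIRC6", "cautionary_pp_sv", "DUP", "5287", "European", 54, 4.3, 5),
    ("PHC3-PRKACA", "cautionary_pp_sv", "TRA", "SMU061", "African", 65, 12.1, 3),
    ("KCTD3-DST", "cautionary_pp_sv", "TRA", "UP2039", "African", 71, 319, 4),
    ("KCTD3-DST", "cautionary_pp_sv", "TRA", "SMU101", "African", 70, 4.3, 3),
    ("PKHD1", "cautionary_pp_sv", "TRA", "N0056", "African", 70, 153, 5),
    ("PKHD1", "cautionary_pp_sv", "TRA", "SMU196", "African", 47, 9.5, 1),
]

#: distinct African carriers eligible (GG >= 3): 16; cohort target 93
_AFRICAN_FILLER_GG3 = 77
#: distinct European carriers at GG >= 4: 4; cohort target 49
_EUROPEAN_FILLER_GG4 = 45


def reference_calls() -> list[PathogenicityCall]:
    seen = {}
    for label, tier, _, _, _, _, _, _ in CARRIER_ROWS:
        seen[label] = tier
    return [PathogenicityCall(sv_id=label, tier=tier) for label, tier in seen.items()]


def reference_carriers() -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for label, _, _, patient, _, _, _, _ in CARRIER_ROWS:
        out.setdefault(label, set()).add(patient)
    return out


def reference_patients() -> list[PatientRecord]:
    patients = {}
    for _, _, _, pid, group, age, psa, gg in CARRIER_ROWS:
        patients[pid] = PatientRecord(
            patient_id=pid, group=group, age=age, psa=psa, isup_gg=gg
        )
    n_afr = sum(1 for p in patients.values() if p.group == "African")
    n_eur = len(patients) - n_afr
    for i in range(N_AFRICAN - n_afr):
        gg = 3 if i < _AFRICAN_FILLER_GG3 else 1
        patients[f"AFILL{i:03d}"] = PatientRecord(
            patient_id=f"AFILL{i:03d}", group="African", isup_gg=gg
        )
    for i in range(N_EUROPEAN - n_eur):
        gg = 4 if i < _EUROPEAN_FILLER_GG4 else 1
        patients[f"EFILL{i:03d}"] = PatientRecord(
            patient_id=f"EFILL{i:03d}", group="European", isup_gg=gg
        )
    return list(patients.values())
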