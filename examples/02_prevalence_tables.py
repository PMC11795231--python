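"""Crude and true prevalence of skeletal lesions.

Builds a small skeletal sample by hand, then computes crude prevalence
(affected individuals / assessable individuals) and true prevalence
(affected elements / observable elements) for periosteal new bone formation
(PNBF), plus the individual-level PD severity collapse. Unobservable bones
and sockets never enter a denominator.
"""

from dentasym import SkeletalRecord, classify_pnbf, collapse_pd, crude_prevalence, true_prevalence
from dentasym.osteo_records import pnbf_elementwise, pnbf_present

records = [
    SkeletalRecord(
        "sk1", "YB", "mature", "female", 45.0,
        pnbf_elements={("tibia", "L"): "present_active", ("tibia", "R"): "present_remodeled",
                       ("femur", "L"): "absent", ("femur", "R"): "absent"},
        pd_sockets={"socket_1": 2, "socket_2": 1, "socket_3": "x"},
    ),
    SkeletalRecord(
        "sk2", "YB", "mature", "male", 30.0,
        pnbf_elements={("femur", "L"): "absent", ("femur", "R"): "not_observable"},
        pd_sockets={"socket_1": 0, "socket_2": 1},
    ),
    SkeletalRecord(
        "sk3", "YB", "immature", "not_assessed", 9.5,
        pnbf_elements={("tibia", "L"): "not_observable"},  # nothing assessable
        pd_sockets={"socket_1": 0},
    ),
]

for rec in records:
    presence, activity, laterality = classify_pnbf(rec)
    severity = collapse_pd(rec.pd_sockets.values())
    print(f"{rec.individual_id}: PNBF {presence}"
          + (f" ({activity}, {laterality})" if presence == "present" else "")
          + f"; PD severity class {severity} (1 = moderate/severe)")

cpr = crude_prevalence(records, pnbf_present)
tpr = true_prevalence(records, pnbf_elementwise)
print(f"\nPNBF crude prevalence:  {cpr}   <- sk3 is excluded (nothing observable)")
print(f"PNBF true prevalence:   {tpr}   <- counts observable bones, not people")
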