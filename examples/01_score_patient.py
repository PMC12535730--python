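"""Score a single admission with all four risk scores.

A 74-year-old admitted with an exacerbation: heart rate 90, SpO2 92% on
supplemental oxygen, respiratory rate 22, temperature 36.5, systolic BP 138,
alert, normal BUN and pH, eosinopenic, no consolidation, no atrial
fibrillation.
"""

from copdrisk import PatientRecord, compute_bap65, compute_combi, compute_decafm, compute_news

patient = PatientRecord(
    patient_id="example", age=74, sex="male", heart_rate=90, spo2=92,
    on_supplemental_o2=True, respiratory_rate=22, temperature=36.5,
    systolic_bp=138, altered_mental_status=False, bun=5.0, ph=7.40,
    eosinophils=0.03, consolidation_cxr=False, atrial_fibrillation=False,
)

news = compute_news(patient)
bap = compute_bap65(patient)
decafm = compute_decafm(patient)
combi = compute_combi(patient)

print(f"NEWS        : {news.total}  components {news.components}")
print(f"BAP-65      : class {bap.risk_class} ({bap.risk_factors} risk factors)")
print(f"DECAFm      : {decafm.total}  present {[k for k, v in decafm.components.items() if v]}")
print(f"AECOPD-COMBI: {combi.total}  components {combi.components}")
print()
print("The composite gets 6 points for age >= 65 and 4 for eosinopenia on top")
print("of the NEWS vital-sign bands; a total of 16 sits near the cohort's")
print("typical upper-quartile high-risk cut, so this patient is borderline.")
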