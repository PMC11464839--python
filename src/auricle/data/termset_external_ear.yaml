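# Congenital external-ear anomaly case definition: MedDRA Preferred Terms.
# Codes are recorded where reliably known; two entries carry no code because
# the available printed codes were missing or ambiguous (the same code was
# printed for both "low set ears" and "macrotia"), so name matching is
# authoritative throughout the package.
name: congenital-external-ear-anomalies
pt_entries:
  - {pt_name: "Accessory auricle", pt_code: 10000361}
  - {pt_name: "Anomaly of external ear congenital", pt_code: 10062339}
  - {pt_name: "Anotia", pt_code: 10002654}
  - {pt_name: "Congenital aural fistula", pt_code: null}
  - {pt_name: "Constricted ear deformity", pt_code: 10071233}
  - {pt_name: "External auditory canal atresia", pt_code: 10054875}
  - {pt_name: "Low set ears", pt_code: 10024929}
  - {pt_name: "Macrotia", pt_code: null}
  - {pt_name: "Microtia", pt_code: 10027555}
  - {pt_name: "Protuberant ear", pt_code: 10071232}
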