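# MedDRA preferred terms counted as renal/urinary adverse events, one per line.
# A flat, editable PT list standing in for "PTs under the renal and urinary SOC";
# MedDRA licensing prevents bundling the dictionary hierarchy itself, so exact
# replication of a given study requires substituting that study's own PT list.
# Membership tests are case- and whitespace-insensitive.
Acute kidney injury
Renal failure
Renal impairment
Urinary tract infection
Tubulointerstitial nephritis
Chronic kidney disease
Nephritis
Hematuria
Urinary retention
Chromaturia
Nephrotic syndrome
Glomerulonephritis
Proteinuria
Renal tubular necrosis
Hydronephrosis
Nephrolithiasis
Oliguria
Anuria
Dysuria
Pollakiuria
Renal colic
Nephropathy toxic
Renal disorder
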