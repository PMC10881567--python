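# Curated extensions to the core rulebase.  The core rules leave some
# well-established biomarker patterns uncovered: hypometabolism with
# medial-temporal atrophy for early MCI, and the amnestic profile (high
# ADAS13, near-total delayed forgetting, elevated CSF tau) for late MCI.
# These rules add that coverage and give every class redundancy so that
# records with missing features can still be diagnosed.

RULE e1: IF MMSE IS VeryHigh AND MOCA IS VeryHigh AND FDG IS VeryHigh AND S_Severity IS Low AND C_Severity IS Low THEN DR IS CN;
RULE e2: IF CDRSB IS VeryLow AND MOCA IS High AND FDG IS High AND S_Severity IS Low AND C_Severity IS Low THEN DR IS SMC;
RULE e3: IF FDG IS Low AND Hippocampus IS Low AND MidTemp IS Low AND S_Severity IS Average AND C_Severity IS Average THEN DR IS EMCI;
RULE e4: IF FDG IS Low AND Hippocampus IS Low AND MMSE IS Medium AND S_Severity IS Average THEN DR IS EMCI;
RULE e5: IF ADAS13 IS High AND RAVLT_perc_forgetting IS VeryHigh AND TAU IS High AND S_Severity IS Average AND C_Severity IS Average THEN DR IS LMCI;
RULE e6: IF ADAS13 IS High AND Ventricles IS High AND PTAU IS High AND LDELTOTAL IS VeryHigh AND S_Severity IS Average THEN DR IS LMCI;
RULE e7: IF FAQ IS VeryHigh AND ADAS13 IS VeryHigh AND MMSE IS VeryLow AND S_Severity IS High AND C_Severity IS High THEN DR IS AD;
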