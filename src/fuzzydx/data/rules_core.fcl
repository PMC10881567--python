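# Core expert rulebase: 18 diagnostic rules spanning the five classes.
# Severity atoms (S_Severity, C_Severity) are bound at runtime from the
# symptom/complication taxonomy, which is what makes the rulebase dynamic
# with respect to open-vocabulary symptom text.

RULE c1: IF CDRSB IS VeryLow AND FAQ IS VeryLow AND ADAS13 IS VeryLow AND MMSE IS VeryHigh AND MOCA IS VeryHigh AND FDG IS VeryHigh AND S_Severity IS Low AND C_Severity IS Low THEN DR IS CN;
RULE c2: IF CDRSB IS VeryLow AND FAQ IS VeryLow AND ADAS13 IS VeryLow AND MMSE IS VeryHigh AND FDG IS VeryHigh AND S_Severity IS Low AND C_Severity IS Low THEN DR IS CN;
RULE c3: IF CDRSB IS VeryLow AND FAQ IS VeryLow AND ADAS13 IS VeryLow AND MMSE IS VeryHigh AND MOCA IS VeryHigh AND S_Severity IS Low AND C_Severity IS Low THEN DR IS CN;
RULE c4: IF CDRSB IS VeryLow AND Age IS Old AND MOCA IS VeryHigh AND Hippocampus IS High AND S_Severity IS Low AND C_Severity IS Low THEN DR IS CN;
RULE c5: IF CDRSB IS VeryLow AND Age IS Old AND MOCA IS VeryHigh AND Hippocampus IS High AND FDG IS VeryHigh AND RAVLT_immediate IS High AND S_Severity IS Low AND C_Severity IS Low THEN DR IS CN;
RULE c6: IF CDRSB IS VeryLow AND MOCA IS VeryHigh AND FAQ IS Low AND RAVLT_perc_forgetting IS Low AND FDG IS VeryHigh AND S_Severity IS Low AND C_Severity IS Low THEN DR IS CN;
RULE c7: IF CDRSB IS VeryLow AND LDELTOTAL IS High AND S_Severity IS Low AND C_Severity IS Low THEN DR IS CN;
RULE c8: IF CDRSB IS VeryLow and FDG IS High and LDELTOTAL IS High AND S_Severity IS Low AND C_Severity IS Low THEN DR IS SMC;
RULE c9: IF CDRSB IS VeryLow AND MOCA IS High AND S_Severity IS Low AND C_Severity IS Low THEN DR IS SMC;
RULE c10: IF MMSE IS Medium AND LDELTOTAL IS High AND CDRSB IS Low AND S_Severity IS Average AND C_Severity IS Average THEN DR IS EMCI;
RULE c11: IF MMSE IS Medium AND LDELTOTAL IS Medium AND Education IS High AND S_Severity IS Average AND C_Severity IS Average THEN DR IS EMCI;
RULE c12: IF MMSE IS Medium AND LDELTOTAL IS High AND CDRSB IS Low AND MOCA IS VeryHigh AND S_Severity IS Average AND C_Severity IS Average THEN DR IS EMCI;
RULE c13: IF CDRSB IS Medium AND FAQ IS High AND LDELTOTAL IS Medium AND S_Severity IS Average AND C_Severity IS Average THEN DR IS EMCI;
RULE c14: IF CDRSB IS Medium AND FAQ IS High AND LDELTOTAL IS Low AND S_Severity IS Average AND C_Severity IS Average THEN DR IS LMCI;
RULE c15: IF CDRSB IS Medium AND FAQ IS High AND LDELTOTAL IS Medium AND Education IS VeryHigh AND S_Severity IS Average AND C_Severity IS Average THEN DR IS LMCI;
RULE c16: IF FAQ IS VeryHigh AND CDRSB IS High AND S_Severity IS High AND C_Severity IS High THEN DR IS AD;
RULE c17: IF FAQ IS VeryHigh AND MMSE IS VeryLow AND S_Severity IS High AND C_Severity IS High THEN DR IS AD;
RULE c18: IF FAQ IS VeryHigh AND MOCA IS Low AND S_Severity IS High AND C_Severity IS High THEN DR IS AD;
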