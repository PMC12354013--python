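"""Reference constants for the histone H4 tail acylation system.

Rates are relative first-order rate constants in min^-1, fitted under
substrate excess (500 uM H4 tail, 5 mM acyl-CoA, 5 uM enzyme) so that k
approximates k_cat.  Chemical shifts are in ppm; masses in Da.
"""

from __future__ import annotations

# --- fitted relative rate constants (min^-1) ------------------------------

#: Mono-exponential acetylation rates for wild-type p300 and the
#: autoinhibitory-loop truncation mutant p300Δ.
ACETYL_MONO_K = {"p300": 0.0273, "p300d": 0.0312}

#: Bi-exponential acetylation rates (k1 fast, k2 slow).  The fast class
#: contains the three preferred sites (K5, K8, K12), the slow class the
#: two remaining ones (K16, K20); amplitudes split ~60%/40%.
ACETYL_BI_K = {"p300": (0.0455, 0.0122), "p300d": (0.0473, 0.0156)}

#: Mono-exponential propionylation rates.
PROPIONYL_MONO_K = {"p300": 0.0085, "p300d": 0.0086}

#: Lagged mono-exponential propionylation fits: (k in min^-1, t0 in min).
PROPIONYL_LAGGED = {"p300": (0.0073, 25.39), "p300d": (0.0081, 24.37)}

# --- H4 tail substrate -----------------------------------------------------

#: H4(1-25) with an exogenous C-terminal tryptophan for staining.
H4_TAIL_SEQUENCE = "SGRGKGGKGLGKGGAKRHRKVLRDNW"

#: The five modifiable lysines, N- to C-terminal.
H4_SITE_LABELS = ("K5", "K8", "K12", "K16", "K20")

FAST_SITES = ("K5", "K8", "K12")
SLOW_SITES = ("K16", "K20")

# --- acquisition defaults --------------------------------------------------

#: Minutes per HSQC experiment ("3 min and 36 s").
EXPERIMENT_LENGTH_MIN = 3.6

#: Default deadtime between cofactor mixing and the start of experiment 2.
DEFAULT_DEADTIME_MIN = 5.0

#: Default number of post-initiation experiments (~4 h span).
DEFAULT_N_EXPERIMENTS = 67

# --- resonance catalog (1H ppm, 13C ppm) ----------------------------------

ACETYLLYSINE = (1.86, 22.1)
PROPIONYLLYSINE = (2.35, 27.37)            # well-resolved methyl resonance
PROPIONYLLYSINE_METHYLENE = (2.12, 29.37)  # partially overlapped
# Only the 1H shift of acetyl-CoA (2.25 ppm) is observed; the 13C
# coordinate 30.2 ppm is a synthetic convention for spectrum generation.
ACETYL_COA = (2.25, 30.2)
PROPIONYL_COA_METHYL = (1.00, 9.23)
PROPIONYL_COA_METHYLENE = (2.49, 37.08)
PROPIONATE_METHYL = (0.95, 10.05)
PROPIONATE_METHYLENE = (2.08, 30.72)

#: F2 (1H) extraction windows in ppm, (low, high).
AC_WINDOW_PPM = (1.84, 1.89)
PR_WINDOW_PPM = (2.34, 2.38)

#: Raw F2 index boundaries as recorded during processing; stored as
#: metadata only — the index↔ppm mapping depends on unprinted processing
#: parameters and is not used for extraction.
AC_WINDOW_INDICES = (624, 628)
PR_WINDOW_INDICES = (573, 577)

# --- mass arithmetic (Da, monoisotopic) ------------------------------------

PROTON_MASS = 1.00727646688
#: Mass excess of 13C over 12C.
C13_DELTA = 1.0033548378
#: Acetyl (CH2CO) and propionyl (C2H4CO) additions to a lysine epsilon-amine.
ACETYL_SHIFT = 42.0105646863
PROPIONYL_SHIFT = 56.0262147306
#: Labeled carbons transferred per acyl group: 1,1',2,2'-13C acetic
#: anhydride gives a 2-carbon 13C-acetyl; 13C6 propionic anhydride a
#: 3-carbon 13C-propionyl.
LABELED_CARBONS = {"acetyl": 2, "propionyl": 3}
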