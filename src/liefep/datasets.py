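"""Published IRAP/HFI benchmark tables.

The HFI series are benzopyran-based inhibitors of insulin-regulated
aminopeptidase (IRAP).  The tables below transcribe the published
experimental inhibition constants and the reported LIE/FEP results for that
series — the standard benchmark for this analysis chain:

* wild-type affinity series: Ki (μM, ">100" = censored non-binder),
  LIE-calculated ΔG ± SEM, experimental ΔG (kcal/mol);
* compounds 6–9 measured against wild-type IRAP and the F544I / F544V
  mutants (LIE vs experiment);
* ligand-transformation ΔΔG edges (FEP vs experiment) for the closed
  thermodynamic cycle 9→8→6←7←9, per enzyme form;
* residue-mutation scan at position 544: per-compound wt→Ala and mut→Ala
  FEP legs with the combined F544I / F544V shifts and experimental values.

All free energies in kcal/mol.  These frames are inputs for the evaluation
and cycle routines; the package does not re-run the underlying molecular
dynamics.
"""

from __future__ import annotations

import io

import pandas as pd

_WT_AFFINITY_CSV = """\
compound_id,ki_uM,censored,dg_calc,dg_calc_sem,dg_exp
15a,100,True,-5.26,0.12,-5.45
15b,100,True,-5.35,0.11,-5.45
15c,50,False,-5.56,0.12,-5.86
15d,100,True,-5.83,0.14,-5.45
15e,100,True,-6.05,0.17,-5.45
15f,100,True,-5.03,0.26,-5.45
15g,100,True,-5.40,0.14,-5.45
16a,100,True,-5.46,0.17,-5.45
16b,100,True,-5.61,0.19,-5.45
16c,2.9,False,-6.67,0.19,-7.55
16d,3,False,-7.64,0.09,-7.53
16e,42,False,-7.01,0.08,-5.96
16f,35,False,-7.15,0.14,-6.07
16g,3.2,False,-7.37,0.11,-7.49
16h,14,False,-7.38,0.18,-6.61
16i,100,True,-5.24,0.10,-5.45
16j,100,True,-6.00,0.11,-5.45
16k,100,True,-5.86,0.16,-5.45
16l,11,False,-7.55,0.08,-6.76
16m,3.7,False,-7.23,0.07,-7.40
16n,0.9,False,-7.93,0.17,-8.24
16o,7.7,False,-7.83,0.22,-6.97
16p,100,True,-5.96,0.18,-5.45
16q,5.3,False,-7.57,0.20,-7.19
16r,6.2,False,-7.72,0.21,-7.10
17a,4.9,False,-6.86,0.07,-7.24
17b,1.6,False,-7.13,0.14,-7.90
17c,2.6,False,-7.07,0.17,-7.61
17d,11.9,False,-7.15,0.15,-6.71
17e,4,False,-6.97,0.20,-7.36
17g,1.7,False,-7.31,0.08,-7.86
18d,5.6,False,-7.33,0.24,-7.16
18f,9.8,False,-6.79,0.21,-6.83
18g,100,True,-7.47,0.10,-5.45
18h,100,True,-5.49,0.21,-5.45
"""

_MUTANT_AFFINITY_CSV = """\
compound_id,enzyme,dg_calc,dg_calc_sem,dg_exp,dg_exp_sem
6,wt,-8.17,0.4,-7.76,0.26
7,wt,-8.73,0.4,-8.83,0.43
8,wt,-8.56,0.1,-8.35,0.41
9,wt,-9.09,0.2,-10.23,0.13
6,F544I,-7.71,0.4,-6.52,0.33
7,F544I,-7.29,0.1,-7.40,0.17
8,F544I,-7.53,0.1,-7.82,0.19
9,F544I,-8.09,0.2,-9.13,0.15
6,F544V,-6.61,0.4,-7.34,0.02
7,F544V,-7.54,0.2,-7.63,0.21
8,F544V,-8.26,0.1,-8.41,0.20
9,F544V,-8.34,0.2,-8.95,0.30
"""

# Ligand transformation edges, ΔΔG on the B − A convention.
_TRANSFORMATION_CSV = """\
enzyme,a_label,b_label,ddg_fep,ddg_fep_sem,ddg_exp,ddg_exp_sem
wt,8,6,0.68,0.70,0.58,0.34
wt,7,6,1.10,0.46,1.07,0.36
wt,9,8,1.90,0.18,1.89,0.30
wt,9,7,1.38,0.50,1.40,0.32
F544I,8,6,1.44,0.98,1.30,0.27
F544I,7,6,0.87,0.29,0.88,0.26
F544I,9,8,1.39,0.20,1.31,0.17
F544I,9,7,0.74,0.37,1.73,0.16
F544V,8,6,1.04,0.65,1.07,0.14
F544V,7,6,0.61,0.24,0.29,0.15
F544V,9,8,0.78,0.30,0.54,0.26
F544V,9,7,1.40,0.25,1.32,0.26
"""

# Residue-mutation scan at position 544, ΔΔG on the mut − wt convention.
# wt→Ala (F544A) and mut→Ala (I544A / V544A) are FEP legs; the combined
# F544I / F544V columns and the experimental values are for comparison.
_MUTATION_SCAN_CSV = """\
compound_id,f544a,f544a_sem,i544a,i544a_sem,v544a,v544a_sem,f544i,f544i_sem,f544i_exp,f544i_exp_sem,f544v,f544v_sem,f544v_exp,f544v_exp_sem
6,0.93,0.20,-0.35,0.19,0.41,0.18,1.28,0.19,1.24,0.29,0.52,0.19,0.42,0.18
7,0.92,0.20,-0.73,0.20,-0.59,0.29,1.66,0.20,1.43,0.33,1.51,0.25,1.20,0.34
8,0.31,0.17,-0.21,0.21,0.36,0.11,0.52,0.19,0.53,0.32,-0.06,0.15,-0.07,0.32
9,1.10,0.22,-0.41,0.18,-0.48,0.15,1.51,0.20,1.10,0.14,1.58,0.19,1.28,0.23
"""


def _read(csv: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(csv))


def wt_affinity_table() -> pd.DataFrame:
    """Wild-type HFI affinity series (Ki, LIE ΔG calc, ΔG exp).

    ``censored`` rows are assay non-binders (Ki > 100 μM); their ki_uM and
    dg_exp columns hold the censoring bound, not a measurement.
    """
    df = _read(_WT_AFFINITY_CSV)
    df["compound_id"] = df["compound_id"].astype(str)
    return df


def mutant_affinity_table() -> pd.DataFrame:
    """Compounds 6–9 against wild-type, F544I and F544V IRAP (LIE vs experiment)."""
    df = _read(_MUTANT_AFFINITY_CSV)
    df["compound_id"] = df["compound_id"].astype(str)
    return df


def transformation_table() -> pd.DataFrame:
    """Ligand-transformation ΔΔG edges (B − A) per enzyme form, FEP vs experiment."""
    df = _read(_TRANSFORMATION_CSV)
    df["a_label"] = df["a_label"].astype(str)
    df["b_label"] = df["b_label"].astype(str)
    return df


def mutation_scan_table() -> pd.DataFrame:
    """Position-544 mutation scan: Ala-intermediate legs and combined shifts."""
    df = _read(_MUTATION_SCAN_CSV)
    df["compound_id"] = df["compound_id"].astype(str)
    return df


def evaluation_pairs(which: str = "all") -> list[tuple[float, float]]:
    """(calc, exp) pairs for benchmark evaluation, censored rows excluded.

    ``which``: 'wt' for the 25 wild-type pairs (21 uncensored series rows
    plus compounds 6–9 on wt), 'mutants' for the 8 mutant pairs, 'all' for
    all 33.
    """
    wt = wt_affinity_table()
    mut = mutant_affinity_table()
    pairs: list[tuple[float, float]] = []
    if which in ("wt", "all"):
        unc = wt[~wt["censored"]]
        pairs += list(zip(unc["dg_calc"], unc["dg_exp"]))
        w = mut[mut["enzyme"] == "wt"]
        pairs += list(zip(w["dg_calc"], w["dg_exp"]))
    if which in ("mutants", "all"):
        m = mut[mut["enzyme"] != "wt"]
        pairs += list(zip(m["dg_calc"], m["dg_exp"]))
    if not pairs:
        raise ValueError(f"unknown subset {which!r}")
    return pairs
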