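"""Shared index layout for the packed state and parameter vectors.

The ODE kernel (numba) and the high-level API exchange plain float64
arrays; every index below is part of that contract.
"""

# ---- state vector ----------------------------------------------------
I_T = 0        # viable tumor cells
I_TD = 1       # damaged tumor cells
I_EI = 2       # inactive CD8+ T cells
I_EA = 3       # active CD8+ (first proliferation stage)
I_EP1 = 4      # proliferating stages EP1..EP7 -> 4..10
I_EP7 = 10
I_ED10 = 11    # CTLs with remaining kill capacity 10..1 -> 11..20
I_ED1 = 20
I_ED0 = 21     # exhausted CTLs
I_DEPOT1 = 22  # anti-PD-1 IP depot (nmol)
I_AC1 = 23     # anti-PD-1 central amount (nmol)
I_AP1 = 24     # anti-PD-1 peripheral amount (nmol)
I_DEPOT2 = 25  # anti-PD-L1 IP depot
I_AC2 = 26     # anti-PD-L1 central amount
I_AP2 = 27     # anti-PD-L1 peripheral amount
NSTATE = 28

N_PROLIF_STAGES = 8      # EA plus EP1..EP7
N_KILLS_PER_CTL = 10     # remaining-capacity ladder ED10..ED1

# ---- parameter vector ------------------------------------------------
P_KPFR = 0
P_KLIMIT = 1
P_EMAX_INFLUX = 2
P_KS_IVT = 3
P_EC50 = 4
P_XREF = 5
P_EMAX_ACT = 6
P_KA2I = 7
P_KD_CD8 = 8
P_KD_CTL = 9
P_KTR = 10          # ln2 / Thalf_CD8pfr
P_KKILL = 11
P_EMAX_ADCC = 12
P_KAPOP = 13
P_RPD1 = 14
P_RPDL1 = 15
P_NOTHER = 16
P_KDPL = 17
P_KDA1 = 18
P_KDAL1 = 19
P_VOID = 20
P_VCELL = 21
P_INFLUX_MODE = 22  # 0 = binding-dependent influx, 1 = constant ks_IVt
P_A1_K10 = 23
P_A1_K12 = 24
P_A1_K21 = 25
P_A1_V1 = 26
P_A1_KA = 27
P_A2_K10 = 28
P_A2_K12 = 29
P_A2_K21 = 30
P_A2_V1 = 31
P_A2_KA = 32
NPAR = 33

# count -> nM conversion: 1/(N_A * 1e-9 mol/nmol * mm3 -> L)
#   conc_nM = count / (AVOGADRO_NM * V_interstitial_mm3)
AVOGADRO_NM = 6.02214076e8
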