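name	value	units	note
ks_mFSH	0.05895	(pg/ug RNA)/hr	basal mFSH synthesis rate
alpha_mFSH_GnRH	2.0917	unitless	GnRH stimulation of mFSH synthesis
kd_mFSH	0.2446	1/hr	mFSH degradation rate
ks_mLH	0.0512	(pg/ug RNA)/hr	basal mLH synthesis rate
alpha_mLH_GnRH	0.01	unitless	GnRH stimulation of mLH synthesis
alpha_mLH_E2	4.15	ml/ng	delayed-E2 stimulation of mLH synthesis
kd_mLH	0.1046	1/hr	mLH degradation rate
ks_LH	1.004	(pg/ug RNA)^-1 ng/mg pituitary/hr	LH synthesis rate from mLH
kd_LH	0.06	1/hr	pituitary LH degradation rate
kr_LH	66700.0	1/hr	LH release rate from pituitary into blood
T_E2_LH	23.0	ng/ml	E2 threshold permitting LH release
n_E2_LH	9.0	unitless	Hill exponent of the E2 gate on LH release
N_E2	36.78	ml/mg pituitary	E2-to-D2-receptor conversion in the release block
N_DHP	2.8	ml/mg pituitary	DHP-to-D2-receptor conversion in the release block
w_Pit	15.0	mg/kg	pituitary weight
V_FSH	156.0	ml/kg	FSH volume of distribution
ks_FSH	0.0138	(pg/ug RNA)^-1 ng/mg pituitary/hr	FSH appearance rate in blood
Cl_FSH	1.7372	ml/hr/kg	FSH plasma clearance
V_LH	156.0	ml/kg	LH volume of distribution
Cl_LH	1.7372	ml/hr/kg	LH plasma clearance
V_E2	261.0	ml/kg	E2 volume of distribution
Cl_E2	22.0	ml/hr/kg	E2 plasma clearance
V_DHP	261.0	ml/kg	DHP volume of distribution
Cl_DHP	57.0	ml/hr/kg	DHP plasma clearance
V_VTGP	240.0	ml/kg	plasma VTG volume of distribution
Cl_VTG_trans	42.2	ml/hr/kg	plasma<->peripheral VTG transfer clearance
Cl_VTG_Seq	170.0	ml/hr/kg	basal ovarian VTG sequestration clearance
T_Seq_FSH	13.7	ng/ml	FSH threshold stimulating VTG sequestration
Cl_VTG	29.3	ml/hr/kg	total-body VTG clearance
V_VTGN	318.0	ml/kg	peripheral VTG volume of distribution
k_E2	0.0053	ng/hr/follicle	basal per-follicle E2 production
n_oocyte	2500.0	follicle/kg	oocyte follicles per kg of fish
Cl_E2_S2	0.00057	ml/hr/follicle	FSH-driven E2 secretion clearance, stage 2
Cl_E2_S3	0.00057	ml/hr/follicle	FSH-driven E2 secretion clearance, stage 3
Cl_E2_S4	0.0027	ml/hr/follicle	FSH-driven E2 secretion clearance, stage 4
Cl_E2_S5	0.0561	ml/hr/follicle	FSH-driven E2 secretion clearance, stage 5
Cl_E2_S6	0.0617	ml/hr/follicle	FSH-driven E2 secretion clearance, stage 6
Cl_DHP_S2	0.0003	ml/hr/follicle	LH-driven DHP secretion clearance, stage 2
Cl_DHP_S3	0.0003	ml/hr/follicle	LH-driven DHP secretion clearance, stage 3
Cl_DHP_S4	0.0003	ml/hr/follicle	LH-driven DHP secretion clearance, stage 4
Cl_DHP_S5	0.0003	ml/hr/follicle	LH-driven DHP secretion clearance, stage 5
Cl_DHP_S6	0.3	ml/hr/follicle	LH-driven DHP secretion clearance, stage 6
Cl_DHP_SFOM	0.79	ml/hr/follicle	LH-driven DHP secretion clearance, FOM
k_NV_OAvg	0.00067	mm/hr	non-vitellogenic follicle growth rate
k_V_OAvg	2.19e-07	mm/mg	growth per mg VTG sequestered per follicle
alpha_OVar_S1	0.0214	mm^2	maximal diameter variance, stage 1
alpha_OVar_S2	0.0433	mm^2	maximal diameter variance, stage 2
alpha_OVar_S3	0.0748	mm^2	maximal diameter variance, stage 3
alpha_OVar_S4	0.0907	mm^2	maximal diameter variance, stage 4
alpha_OVar_S5	0.0338	mm^2	maximal diameter variance, stage 5
alpha_OVar_S6	0.014	mm^2	maximal diameter variance, stage 6
alpha_OVar_SFOM	0.0067	mm^2	maximal diameter variance, FOM
s_1	0.2	mm	diameter dividing stages 1 and 2
s_2	0.6	mm	diameter dividing stages 2 and 3 (VTG uptake begins)
s_3	1.17	mm	diameter dividing stages 3 and 4
s_4	1.69	mm	diameter dividing stages 4 and 5
s_5	3.4	mm	diameter dividing stages 5 and 6
s_6	5.3	mm	diameter dividing stage 6 and FOM
FOM_final	0.98	unitless	FOM proportion required for ovulation
DHP_final	120.0	ng/ml	DHP concentration required for ovulation
w_L	15.0	g/kg	liver weight
ks_mR	30.0	(pg/ug RNA)/hr	basal mR synthesis rate
alpha_mR_ER	0.0667	g liver/fmol	ER stimulation of mR synthesis
kd_mR	0.5	1/hr	mR degradation rate
ks_R	0.0113	(pg/ug RNA)^-1 fmol/g liver/hr	receptor synthesis rate from mR
kd_R	0.466	1/hr	free receptor degradation rate
kon_ER	0.826	(ng/ml)^-1 1/hr	E2-receptor association rate
koff_ER	0.347	1/hr	E2-receptor dissociation rate
kd_ER	0.0766	1/hr	E2-receptor complex degradation rate
ks_mVTG	6.93e-05	(pg/ug RNA)/hr	basal mVTG synthesis rate
alpha_mVTG_ER	5456000.0	g liver/fmol	ER stimulation of mVTG synthesis
kd_mVTG	0.00462	1/hr	mVTG degradation rate
ks_VTG	9.02e-06	mg/g liver/hr	VTG synthesis rate
N_mVTG	1000.0	pg/ug RNA	nondimensionalising scale for mVTG
gamma	2.48	unitless	translational amplification exponent for VTG
kr_VTG	7.87	1/hr	VTG release rate from liver into plasma
D_FSH_E2	875.0	hr	delay of E2 synthesis behind plasma FSH
D_E2_mLH	240.0	hr	delay of mLH synthesis behind plasma E2
D_LH_DHP	72.0	hr	delay of DHP synthesis behind plasma LH
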