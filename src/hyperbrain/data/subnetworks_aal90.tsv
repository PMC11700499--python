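roi	subnetwork
Precentral_L	unassigned
Precentral_R	unassigned
Frontal_Sup_L	DAN
Frontal_Sup_R	DAN
Frontal_Sup_Orb_L	FPN
Frontal_Sup_Orb_R	FPN
Frontal_Mid_L	FPN
Frontal_Mid_R	FPN
Frontal_Mid_Orb_L	FPN
Frontal_Mid_Orb_R	FPN
Frontal_Inf_Oper_L	VAN
Frontal_Inf_Oper_R	VAN
Frontal_Inf_Tri_L	FPN
Frontal_Inf_Tri_R	FPN
Frontal_Inf_Orb_L	FPN
Frontal_Inf_Orb_R	FPN
Rolandic_Oper_L	VAN
Rolandic_Oper_R	VAN
Supp_Motor_Area_L	unassigned
Supp_Motor_Area_R	unassigned
Olfactory_L	unassigned
Olfactory_R	unassigned
Frontal_Sup_Medial_L	aDMN
Frontal_Sup_Medial_R	aDMN
Frontal_Med_Orb_L	aDMN
Frontal_Med_Orb_R	aDMN
Rectus_L	aDMN
Rectus_R	aDMN
Insula_L	SN
Insula_R	SN
Cingulum_Ant_L	SN
Cingulum_Ant_R	SN
Cingulum_Mid_L	SN
Cingulum_Mid_R	SN
Cingulum_Post_L	pDMN
Cingulum_Post_R	pDMN
Hippocampus_L	pDMN
Hippocampus_R	pDMN
ParaHippocampal_L	pDMN
ParaHippocampal_R	pDMN
Amygdala_L	SN
Amygdala_R	SN
Calcarine_L	VN
Calcarine_R	VN
Cuneus_L	VN
Cuneus_R	VN
Lingual_L	VN
Lingual_R	VN
Occipital_Sup_L	VN
Occipital_Sup_R	VN
Occipital_Mid_L	VN
Occipital_Mid_R	VN
Occipital_Inf_L	unassigned
Occipital_Inf_R	unassigned
Fusiform_L	unassigned
Fusiform_R	unassigned
Postcentral_L	unassigned
Postcentral_R	unassigned
Parietal_Sup_L	DAN
Parietal_Sup_R	DAN
Parietal_Inf_L	DAN
Parietal_Inf_R	DAN
SupraMarginal_L	VAN
SupraMarginal_R	VAN
Angular_L	pDMN
Angular_R	pDMN
Precuneus_L	pDMN
Precuneus_R	pDMN
Paracentral_Lobule_L	SMN
Paracentral_Lobule_R	SMN
Caudate_L	unassigned
Caudate_R	unassigned
Putamen_L	unassigned
Putamen_R	unassigned
Pallidum_L	unassigned
Pallidum_R	unassigned
Thalamus_L	SN
Thalamus_R	SN
Heschl_L	VAN
Heschl_R	VAN
Temporal_Sup_L	VAN
Temporal_Sup_R	VAN
Temporal_Pole_Sup_L	VAN
Temporal_Pole_Sup_R	VAN
Temporal_Mid_L	VAN
Temporal_Mid_R	VAN
Temporal_Pole_Mid_L	unassigned
Temporal_Pole_Mid_R	unassigned
Temporal_Inf_L	unassigned
Temporal_Inf_R	unassigned
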