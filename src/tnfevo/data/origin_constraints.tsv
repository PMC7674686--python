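# Origin model for the 24 TNF-superfamily orthology groups.
#
# origin: pre_WGD | WGD1 | WGD2 | tandem | unconstrained.
# For tandem origins, parent_group names the duplicated group and branch the
# child node of the branch on which the duplication happened (on a WGD-bearing
# branch a tandem is placed after the last WGD of that branch).
# progenitor labels the pre-WGD lineage; sublineage distinguishes the post-WGD1
# copies of a progenitor so that each (progenitor, sublineage) WGD2 quartet
# holds at most four ohnologs. paralogon is the ancestral chromosome (9 or 16).
group	cluster	origin	parent_group	branch	progenitor	sublineage	paralogon
TNFSF1/2	TNF	WGD2			P_chr9	TNF	9
TNFSF15	TNF	WGD2			P_chr9	TNF	9
TNFSF6	FASL	WGD2			P_chr9	FASL	9
TNFSF14	FASL	WGD2			P_chr9	FASL	9
TNFSF4	4-1BBL	WGD2			P_chr9	41BBL	9
TNFSF9	4-1BBL	WGD2			P_chr9	41BBL	9
EDA	EDA	WGD2			P_chr16_EDA		16
TNFSF13	EDA	WGD2			P_chr16_EDA		16
TNFSF13B	EDA	WGD2			P_chr16_EDA		16
TNFSF5	CD40L	WGD2			P_chr16_CD40L		16
TNFSF10	CD40L	WGD2			P_chr16_CD40L		16
TNFSF11	CD40L	WGD2			P_chr16_CD40L		16
TNFSF12	CD40L	WGD2			P_chr16_CD40L		16
BALM	EDA	tandem	EDA	vertebrate_ancestor			16
TNFSF-Fish2	TNF	tandem	TNFSF15	vertebrate_ancestor			9
TNFSF3	TNF	tandem	TNFSF1/2	sarcopterygian_ancestor			9
TNFSF8	TNF	tandem	TNFSF15	sarcopterygian_ancestor			9
TNFSF7	4-1BBL	tandem	TNFSF9	Homo_sapiens			9
TNFSF18	4-1BBL	tandem	TNFSF4	Homo_sapiens			9
TNFSF-New	TNF	tandem	TNFSF1/2	teleost_ancestor			9
TNFSF-Fish3	CD40L	tandem	TNFSF5	gnathostome_ancestor			16
TNFSF-Fish4	CD40L	tandem	TNFSF5	gnathostome_ancestor			16
TNFSF-Fish5	TNF	tandem	TNFSF15	gnathostome_ancestor			9
TNFSF-Fish1	unassigned	unconstrained					unknown
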