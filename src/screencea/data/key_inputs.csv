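parameter,value,scale,distribution,source
dbt.recall_rate,9.00,percent,beta,screening cohort (Taiwan medical center)
dbt.slice_rate,34.69,percent,beta,screening cohort (Taiwan medical center)
dbt.ppv2,27.80,percent,beta,screening cohort (Taiwan medical center)
dbt.cancer_detection_rate,8.68,permille,derived,screening cohort (Taiwan medical center)
mg.recall_rate,11.81,percent,beta,screening cohort (Taiwan medical center)
mg.slice_rate,20.56,percent,beta,screening cohort (Taiwan medical center)
mg.ppv2,31.10,percent,beta,screening cohort (Taiwan medical center)
mg.cancer_detection_rate,7.55,permille,derived,screening cohort (Taiwan medical center)
survival.s5.0,97.70,percent,beta,Taiwan cancer registry
survival.s5.1,95.70,percent,beta,Taiwan cancer registry
survival.s5.2,89.10,percent,beta,Taiwan cancer registry
survival.s5.3,72.30,percent,beta,Taiwan cancer registry
survival.s5.4,25.70,percent,beta,Taiwan cancer registry
dbt.stage_dist.0,30.40,percent,beta,screening cohort & cancer registry
dbt.stage_dist.1,31.54,percent,beta,screening cohort & cancer registry
dbt.stage_dist.2,23.94,percent,beta,screening cohort & cancer registry
dbt.stage_dist.3,8.73,percent,beta,screening cohort & cancer registry
dbt.stage_dist.4,5.39,percent,beta,screening cohort & cancer registry
mg.stage_dist.0,18.30,percent,beta,screening cohort & cancer registry
mg.stage_dist.1,31.09,percent,beta,screening cohort & cancer registry
mg.stage_dist.2,31.83,percent,beta,screening cohort & cancer registry
mg.stage_dist.3,11.61,percent,beta,screening cohort & cancer registry
mg.stage_dist.4,7.17,percent,beta,screening cohort & cancer registry
mg.missed_stage_dist.0,0.00,percent,fixed,assumption (no stage-0 among missed cancers)
mg.missed_stage_dist.1,38.05,percent,beta,cancer registry incidence
mg.missed_stage_dist.2,38.96,percent,beta,cancer registry incidence
mg.missed_stage_dist.3,14.21,percent,beta,cancer registry incidence
mg.missed_stage_dist.4,8.77,percent,beta,cancer registry incidence
cost.dbt_exam,150.00,usd,gamma,self-funded examination rate
cost.mg_exam,41.50,usd,gamma,NHI reimbursement rate
cost.revisit_direct,65.38,usd,gamma,NHI reimbursement rate
cost.biopsy_direct,525.67,usd,gamma,NHI payment criteria
cost.treatment_direct.0,6202.80,usd,gamma,lifetime expenditure study
cost.treatment_direct.1,76506.48,usd,gamma,lifetime expenditure study
cost.treatment_direct.2,82421.77,usd,gamma,lifetime expenditure study
cost.treatment_direct.3,93272.99,usd,gamma,lifetime expenditure study
cost.treatment_direct.4,69446.35,usd,gamma,lifetime expenditure study
cost.death_direct,0.00,usd,fixed,assumption
cost.revisit_indirect,43.83,usd,gamma,productivity-loss derivation
cost.biopsy_indirect,41.74,usd,gamma,productivity-loss derivation
cost.treatment_indirect.0,609.64,usd,gamma,morbidity indirect-cost study
cost.treatment_indirect.1,609.64,usd,gamma,morbidity indirect-cost study
cost.treatment_indirect.2,609.64,usd,gamma,morbidity indirect-cost study
cost.treatment_indirect.3,609.64,usd,gamma,morbidity indirect-cost study
cost.treatment_indirect.4,609.64,usd,gamma,morbidity indirect-cost study
cost.death_indirect,5305.34,usd,gamma,mortality indirect-cost study
utility.first_year.0,0.904,utility,gamma,stage-specific utility study
utility.after_first_year.0,1.000,utility,gamma,stage-specific utility study
utility.first_year.1,0.846,utility,gamma,stage-specific utility study
utility.after_first_year.1,0.985,utility,gamma,stage-specific utility study
utility.first_year.2,0.846,utility,gamma,stage-specific utility study
utility.after_first_year.2,0.985,utility,gamma,stage-specific utility study
utility.first_year.3,0.753,utility,gamma,stage-specific utility study
utility.after_first_year.3,0.932,utility,gamma,stage-specific utility study
utility.first_year.4,0.753,utility,gamma,stage-specific utility study
utility.after_first_year.4,0.832,utility,gamma,stage-specific utility study
utility.healthy,1.000,utility,fixed,assumption
utility.death,0.000,utility,fixed,assumption
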