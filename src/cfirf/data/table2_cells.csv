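theme_id,group_id,status,endorsers
technical_logistical_referral,purveyors,barrier,3
technical_logistical_referral,intermediaries,barrier,4
technical_logistical_referral,tfm,barrier,4
technical_logistical_referral,dcj,below_threshold,
outcome_measures_data_collection,purveyors,below_threshold,
outcome_measures_data_collection,intermediaries,barrier,4
outcome_measures_data_collection,tfm,barrier,4
outcome_measures_data_collection,dcj,neutral,
workforce_staffing_resourcing_funding,purveyors,barrier,3
workforce_staffing_resourcing_funding,intermediaries,barrier,4
workforce_staffing_resourcing_funding,tfm,neutral,
workforce_staffing_resourcing_funding,dcj,below_threshold,
evidence_base_aboriginal_families,purveyors,below_threshold,
evidence_base_aboriginal_families,intermediaries,barrier,5
evidence_base_aboriginal_families,tfm,neutral,
evidence_base_aboriginal_families,dcj,below_threshold,
adaptation_nsw_context,purveyors,neutral,
adaptation_nsw_context,intermediaries,barrier,4
adaptation_nsw_context,tfm,neutral,
adaptation_nsw_context,dcj,below_threshold,
eligibility_criteria,purveyors,below_threshold,
eligibility_criteria,intermediaries,below_threshold,
eligibility_criteria,tfm,barrier,3
eligibility_criteria,dcj,neutral,
relationship_service_providers,purveyors,below_threshold,
relationship_service_providers,intermediaries,neutral,
relationship_service_providers,tfm,neutral,
relationship_service_providers,dcj,neutral,
role_policy_expert_contact,purveyors,below_threshold,
role_policy_expert_contact,intermediaries,neutral,
role_policy_expert_contact,tfm,below_threshold,
role_policy_expert_contact,dcj,neutral,
case_management_processes,purveyors,neutral,
case_management_processes,intermediaries,neutral,
case_management_processes,tfm,below_threshold,
case_management_processes,dcj,below_threshold,
implementation_facilitators_barriers,purveyors,below_threshold,
implementation_facilitators_barriers,intermediaries,neutral,
implementation_facilitators_barriers,tfm,neutral,
implementation_facilitators_barriers,dcj,neutral,
role_of_intermediaries,purveyors,below_threshold,
role_of_intermediaries,intermediaries,neutral,
role_of_intermediaries,tfm,neutral,
role_of_intermediaries,dcj,below_threshold,
procurement_contracting,purveyors,below_threshold,
procurement_contracting,intermediaries,below_threshold,
procurement_contracting,tfm,neutral,
procurement_contracting,dcj,below_threshold,
pre_implementation_procedures,purveyors,neutral,
pre_implementation_procedures,intermediaries,below_threshold,
pre_implementation_procedures,tfm,neutral,
pre_implementation_procedures,dcj,below_threshold,
client_snapshot_monitoring,purveyors,below_threshold,
client_snapshot_monitoring,intermediaries,below_threshold,
client_snapshot_monitoring,tfm,enabler,3
client_snapshot_monitoring,dcj,below_threshold,
purveyor_training_support,purveyors,enabler,4
purveyor_training_support,intermediaries,below_threshold,
purveyor_training_support,tfm,below_threshold,
purveyor_training_support,dcj,below_threshold,
fft_cw_program_structure,purveyors,below_threshold,
fft_cw_program_structure,intermediaries,enabler,4
fft_cw_program_structure,tfm,enabler,3
fft_cw_program_structure,dcj,below_threshold,
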