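theme_id,label,n_total
technical_logistical_referral,"Technical, logistical and referral challenges",19
outcome_measures_data_collection,Outcome measures and data collection,14
workforce_staffing_resourcing_funding,"Workforce, staffing, resourcing and funding issues",13
evidence_base_aboriginal_families,Evidence base and appropriateness for Aboriginal families,16
adaptation_nsw_context,Adaptation to NSW context,16
eligibility_criteria,Eligibility criteria of programs,9
relationship_service_providers,Relationship with service providers and other stakeholders,15
role_policy_expert_contact,Role of policy expert/nature of contact with the program,13
case_management_processes,Case management processes,11
implementation_facilitators_barriers,Implementation facilitators and barriers,11
role_of_intermediaries,Role of intermediaries,10
procurement_contracting,Procurement & contracting,9
pre_implementation_procedures,Pre-implementation phase procedures,8
client_snapshot_monitoring,Client snapshot/real-time monitoring of families,5
purveyor_training_support,Model purveyor training and support,6
fft_cw_program_structure,Nature and structure of FFT-CW program,9
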