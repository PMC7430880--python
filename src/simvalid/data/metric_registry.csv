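task,metric,domain,direction,unit
task1,path_length_left,movement,lower_better,mm
task1,path_length_right,movement,lower_better,mm
task1,movements_left,movement,lower_better,count
task1,movements_right,movement,lower_better,count
task1,inaccurate_punctures,safety,lower_better,count
task1,instrument_collisions,safety,lower_better,count
task1,times_out_of_view,safety,lower_better,count
task1,needle_precision,task_specific,higher_better,percent
task1,total_errors,task_specific,lower_better,count
task1,total_time,task_specific,lower_better,seconds
task2,entrance_and_exit_points,movement,lower_better,count
task2,dropped_needles,safety,lower_better,count
task2,unnecessary_piercing,safety,lower_better,count
task2,needle_out_of_view,safety,lower_better,count
task2,suture_breakage,safety,lower_better,count
task2,total_knots,task_specific,higher_better,count
task2,surgeon_knots,task_specific,higher_better,count
task2,needle_precision,task_specific,higher_better,percent
task2,total_time,task_specific,lower_better,seconds
task3,path_length_left,movement,lower_better,mm
task3,path_length_right,movement,lower_better,mm
task3,movements_left,movement,lower_better,count
task3,movements_right,movement,lower_better,count
task3,entrance_and_exit_points,movement,lower_better,count
task3,distance_scope_and_tissue,movement,ambiguous,mm
task3,instrument_collisions,safety,lower_better,count
task3,times_out_of_view,safety,ambiguous,count
task3,unnecessary_piercing,safety,lower_better,count
task3,suture_breakage,safety,lower_better,count
task3,precise_needle_passages,task_specific,lower_better,count
task3,needle_passages,task_specific,lower_better,count
task3,total_time,task_specific,lower_better,seconds
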