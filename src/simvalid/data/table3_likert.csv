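task,metric,group,mean,sd,n
task1,realism,robotic,3.5,0.7,15
task1,realism,laparoscopic,3.5,0.6,26
task1,realism,novice,3.7,0.5,29
task1,realism,total,3.6,0.6,70
task1,didactic_value,robotic,4.0,0.9,15
task1,didactic_value,laparoscopic,3.7,1.0,26
task1,didactic_value,novice,4.0,0.5,29
task1,didactic_value,total,3.9,0.8,70
task1,usability,robotic,3.9,0.6,15
task1,usability,laparoscopic,4.2,0.6,26
task1,usability,novice,4.4,0.5,29
task1,usability,total,4.1,0.6,70
task2,realism,robotic,3.4,0.8,15
task2,realism,laparoscopic,3.8,0.5,26
task2,realism,novice,3.8,0.5,29
task2,realism,total,3.7,0.6,70
task2,didactic_value,robotic,4.0,0.7,15
task2,didactic_value,laparoscopic,4.2,0.5,26
task2,didactic_value,novice,4.2,0.4,29
task2,didactic_value,total,4.1,0.6,70
task2,usability,robotic,3.9,0.6,15
task2,usability,laparoscopic,4.3,0.6,26
task2,usability,novice,4.5,0.5,29
task2,usability,total,4.2,0.6,70
task3,realism,robotic,3.5,0.7,15
task3,realism,laparoscopic,4.1,0.5,26
task3,realism,novice,3.6,0.4,29
task3,realism,total,3.7,0.6,70
task3,didactic_value,robotic,3.9,0.8,15
task3,didactic_value,laparoscopic,4.1,0.8,26
task3,didactic_value,novice,4.1,0.6,29
task3,didactic_value,total,4.0,0.7,70
task3,usability,robotic,4.0,0.7,15
task3,usability,laparoscopic,4.2,0.6,26
task3,usability,novice,4.4,0.5,29
task3,usability,total,4.2,0.6,70
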